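"""Assembly-call mapping, call comparison and confusion metrics."""

import json
import math

import numpy as np
import pytest

from xtalbio.classifier import Call
from xtalbio.comparison import (
    Assembly,
    AssemblyPrediction,
    Stability,
    assembly_to_interface_calls,
    compare_calls,
    confusion_metrics,
    read_assembly_json,
    read_pisa_xml,
)


class FakeInterface:
    def __init__(self, fp):
        self.fingerprint = fp


IF3 = [FakeInterface(f) for f in ("fp1", "fp2", "fp3")]


class TestAssemblyToCalls:
    def test_stable_dimer_marks_members_bio(self):
        pred = AssemblyPrediction("X", [
            Assembly(Stability.STABLE, 2, ["fp1"]),
        ])
        assert assembly_to_interface_calls(pred, IF3) == \
            [Call.BIO, Call.XTAL, Call.XTAL]

    def test_unstable_assemblies_dropped(self):
        pred = AssemblyPrediction("X", [
            Assembly(Stability.UNSTABLE, 4, ["fp1", "fp2", "fp3"]),
            Assembly(Stability.STABLE, 2, ["fp2"]),
        ])
        assert assembly_to_interface_calls(pred, IF3) == \
            [Call.XTAL, Call.BIO, Call.XTAL]

    def test_only_gray_region_gives_no_prediction(self):
        pred = AssemblyPrediction("X", [
            Assembly(Stability.GRAY, 2, ["fp1"]),
            Assembly(Stability.UNSTABLE, 4, []),
        ])
        assert assembly_to_interface_calls(pred, IF3) == [Call.NOPRED] * 3

    def test_largest_stable_assembly_wins(self):
        pred = AssemblyPrediction("X", [
            Assembly(Stability.STABLE, 2, ["fp1"]),
            Assembly(Stability.STABLE, 4, ["fp2", "fp3"]),
        ])
        assert assembly_to_interface_calls(pred, IF3) == \
            [Call.XTAL, Call.BIO, Call.BIO]

    def test_equal_size_tie_takes_first_encountered(self):
        pred = AssemblyPrediction("X", [
            Assembly(Stability.STABLE, 2, ["fp1"]),
            Assembly(Stability.STABLE, 2, ["fp2"]),
        ])
        assert assembly_to_interface_calls(pred, IF3) == \
            [Call.BIO, Call.XTAL, Call.XTAL]

    def test_empty_prediction_abstains(self):
        pred = AssemblyPrediction("X", [])
        assert assembly_to_interface_calls(pred, IF3) == [Call.NOPRED] * 3

    def test_every_interface_covered_once(self):
        pred = AssemblyPrediction("X", [Assembly(Stability.STABLE, 3,
                                                 ["fp1", "fp3"])])
        calls = assembly_to_interface_calls(pred, IF3)
        assert len(calls) == len(IF3)
        assert all(c in (Call.BIO, Call.XTAL) for c in calls)


class TestCompareCalls:
    def test_identical_vectors_full_agreement(self):
        calls = [Call.BIO, Call.XTAL, Call.BIO, Call.XTAL]
        areas = [100.0, 300.0, 500.0, 700.0]
        table = compare_calls(calls, calls, areas)
        assert np.allclose(table["agreement"].dropna(), 1.0)

    def test_complementary_vectors_zero_agreement(self):
        a = [Call.BIO, Call.XTAL]
        b = [Call.XTAL, Call.BIO]
        table = compare_calls(a, b, [100.0, 100.0])
        assert table.iloc[-1]["agreement"] == 0.0

    def test_counted_fixture_agreement(self, rng):
        n, n_match = 100, 88
        a = [Call.BIO] * n
        b = [Call.BIO] * n_match + [Call.XTAL] * (n - n_match)
        areas = list(rng.uniform(0, 2000, n))
        table = compare_calls(a, b, areas)
        assert table.iloc[-1]["agreement"] == pytest.approx(0.88)

    def test_symmetric_overall_agreement(self, rng):
        a = [Call(rng.choice(["BIO", "XTAL", "NOPRED"])) for _ in range(60)]
        b = [Call(rng.choice(["BIO", "XTAL", "NOPRED"])) for _ in range(60)]
        areas = list(rng.uniform(0, 1500, 60))
        t_ab = compare_calls(a, b, areas).iloc[-1]["agreement"]
        t_ba = compare_calls(b, a, areas).iloc[-1]["agreement"]
        assert t_ab == pytest.approx(t_ba, nan_ok=True)

    def test_nopred_pairs_excluded_from_agreement(self):
        a = [Call.BIO, Call.NOPRED]
        b = [Call.BIO, Call.XTAL]
        table = compare_calls(a, b, [100.0, 100.0])
        last = table.iloc[-1]
        assert last["nopred"] == 1 and last["agreement"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_calls([Call.BIO], [], [100.0])


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        truth = ["BIO", "BIO", "XTAL", "XTAL"]
        m = confusion_metrics(truth, truth)
        assert (m.sensitivity, m.specificity, m.accuracy, m.mcc) == (1, 1, 1, 1)

    def test_all_bio_predictor_degenerate(self):
        truth = ["BIO", "BIO", "XTAL", "XTAL"]
        m = confusion_metrics(truth, ["BIO"] * 4)
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.mcc == 0.0 and m.mcc_degenerate

    def test_matches_direct_arithmetic(self):
        # counts reconstructed from a large balanced benchmark
        tp, fn, tn, fp = 2140, 368, 2142, 226
        truth = ["BIO"] * (tp + fn) + ["XTAL"] * (tn + fp)
        calls = (["BIO"] * tp + ["XTAL"] * fn
                 + ["XTAL"] * tn + ["BIO"] * fp)
        m = confusion_metrics(truth, calls)
        assert m.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m.specificity == pytest.approx(tn / (tn + fp), abs=1e-12)
        assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn),
                                           abs=1e-12)
        mcc = ((tp * tn - fp * fn)
               / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        assert m.mcc == pytest.approx(mcc, abs=1e-12)

    def test_nopred_excluded_and_counted(self):
        truth = ["BIO", "BIO", "XTAL"]
        m = confusion_metrics(truth, ["BIO", "NOPRED", "XTAL"])
        assert m.n_excluded == 1 and m.tp == 1 and m.tn == 1

    def test_swapping_positive_class_swaps_sens_spec(self, rng):
        truth = [str(rng.choice(["BIO", "XTAL"])) for _ in range(80)]
        calls = [str(rng.choice(["BIO", "XTAL"])) for _ in range(80)]
        swap = {"BIO": "XTAL", "XTAL": "XTAL" if False else "BIO"}
        m = confusion_metrics(truth, calls)
        m_sw = confusion_metrics([swap[t] for t in truth],
                                 [swap[c] for c in calls])
        assert m.sensitivity == pytest.approx(m_sw.specificity)
        assert m.specificity == pytest.approx(m_sw.sensitivity)
        assert m.accuracy == pytest.approx(m_sw.accuracy)
        assert abs(m.mcc) == pytest.approx(abs(m_sw.mcc))

    def test_empty_evaluable_set_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(["BIO"], ["NOPRED"])


class TestAdapters:
    def test_json_roundtrip(self, tmp_path):
        data = {"entry_id": "TEST",
                "assemblies": [
                    {"stability": "STABLE", "size": 2,
                     "member_interfaces": ["x,y,z|1,0,0"]},
                    {"stability": "gray", "size": 1},
                ]}
        p = tmp_path / "asm.json"
        p.write_text(json.dumps(data))
        pred = read_assembly_json(p)
        assert pred.entry_id == "TEST"
        assert pred.assemblies[0].stability == Stability.STABLE
        assert pred.assemblies[1].stability == Stability.GRAY
        assert pred.assemblies[0].member_interfaces == ["x,y,z|1,0,0"]

    def test_pisa_style_xml(self, tmp_path):
        xml = """<pisa><pdb_code>test</pdb_code>
        <asm_set><assembly><mmsize>2</mmsize><stability>STABLE</stability>
          <interfaces><operator>x,y,z|1,0,0</operator></interfaces>
        </assembly><assembly><mmsize>1</mmsize><diss_energy>1.0</diss_energy>
        </assembly></asm_set></pisa>"""
        p = tmp_path / "asm.xml"
        p.write_text(xml)
        pred = read_pisa_xml(p)
        assert pred.entry_id == "test"
        assert len(pred.assemblies) == 2
        assert pred.assemblies[0].size == 2
        assert pred.assemblies[0].member_interfaces == ["x,y,z|1,0,0"]
        assert pred.assemblies[1].stability == Stability.GRAY
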