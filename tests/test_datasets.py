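"""Benchmark-set construction rules and the area-probability curve."""

import numpy as np
import pytest

from xtalbio.datasets import (
    InterfaceRecord,
    Provenance,
    area_probability_curve,
    build_biomany,
    build_xtalmany,
    cluster_sequences,
    read_records_tsv,
    write_records_tsv,
)

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"          # 33 aa
SEQ_B = SEQ[:30] + "AAA"                            # ~91% identical to SEQ
SEQ_FAR = "GGGGGGGGGGPPPPPPPPPPWWWWWWWWWWNNN"       # unrelated


def record(entry="E1", iface=1, seq_a=SEQ, seq_b=SEQ, area=800.0,
           op="2S", resolution=2.0, **kw):
    defaults = dict(method="XRAY", crystal_form_id="cf1",
                    protcid_cluster_id=None, n_crystal_forms_in_cluster=0,
                    fraction_forms_present=0.0, biounit_symmetry="C2",
                    nmr_matched=False)
    defaults.update(kw)
    return InterfaceRecord(entry, iface, seq_a, seq_b, area, op,
                           resolution, **defaults)


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        recs = [record("E1"), record("E2")]
        assignment, reps = cluster_sequences(recs, 0.8)
        assert assignment[0] == assignment[1]
        assert sum(reps) == 1

    def test_unrelated_sequences_are_singletons(self):
        recs = [record("E1"), record("E2", seq_a=SEQ_FAR, seq_b=SEQ_FAR)]
        assignment, reps = cluster_sequences(recs, 0.8)
        assert assignment[0] != assignment[1]
        assert all(reps)

    def test_single_linkage_chains_transitively(self):
        # A~B and B~C above the cutoff, A~C below: one cluster anyway
        a = SEQ
        b = SEQ[:28] + "AAAAA"      # ~85% to a
        c = SEQ[:23] + "AAAAAAAAAA"  # ~85% to b, ~70% to a
        recs = [record("E1", seq_a=a, seq_b=a),
                record("E2", seq_a=b, seq_b=b),
                record("E3", seq_a=c, seq_b=c)]
        assignment, _ = cluster_sequences(recs, 0.8)
        assert len(set(assignment)) == 1


class TestBioMany:
    def test_protcid_branch_selection(self):
        r = record(protcid_cluster_id="c1", n_crystal_forms_in_cluster=12,
                   fraction_forms_present=0.85, area=1500.0)
        labels = build_biomany([r])
        assert len(labels) == 1
        assert labels[0].label == "BIO"
        assert labels[0].provenance == Provenance.PROTCID

    def test_nmr_branch_selection(self):
        r = record(nmr_matched=True, resolution=1.9, area=550.0)
        labels = build_biomany([r])
        assert len(labels) == 1 and labels[0].provenance == Provenance.NMR

    @pytest.mark.parametrize("forms,fraction,expected", [
        (10, 0.80, 1),   # both at the bound: in
        (9, 0.80, 0),    # one crystal form short: out
        (10, 0.79, 0),   # presence fraction short: out
    ])
    def test_crystal_form_boundaries(self, forms, fraction, expected):
        r = record(protcid_cluster_id="c1", n_crystal_forms_in_cluster=forms,
                   fraction_forms_present=fraction, area=1000.0)
        assert len(build_biomany([r])) == expected

    @pytest.mark.parametrize("area,expected", [
        (500.0, 1),     # at the lower bound: in
        (499.9, 0),     # below: out
    ])
    def test_nmr_area_boundary(self, area, expected):
        r = record(nmr_matched=True, resolution=1.9, area=area)
        assert len(build_biomany([r])) == expected

    @pytest.mark.parametrize("resolution,expected", [(2.49, 1), (2.5, 0)])
    def test_nmr_resolution_strictly_better(self, resolution, expected):
        r = record(nmr_matched=True, resolution=resolution, area=700.0)
        assert len(build_biomany([r])) == expected

    @pytest.mark.parametrize("area,expected", [
        (2000.0, 1),    # at the cap: kept
        (2000.1, 0),    # larger: removed, hard-range policy
        (2400.0, 0),
    ])
    def test_large_area_cap_applies_to_union(self, area, expected):
        protcid = record("E1", protcid_cluster_id="c1",
                         n_crystal_forms_in_cluster=15,
                         fraction_forms_present=0.9, area=area)
        nmr = record("E2", seq_a=SEQ_FAR, seq_b=SEQ_FAR, nmr_matched=True,
                     resolution=1.8, area=area)
        assert len(build_biomany([protcid, nmr])) == 2 * expected

    def test_duplicate_record_counted_once(self):
        r = record(protcid_cluster_id="c1", n_crystal_forms_in_cluster=12,
                   fraction_forms_present=0.9, nmr_matched=True,
                   resolution=1.9, area=900.0)
        labels = build_biomany([r])
        assert len(labels) == 1
        assert labels[0].provenance == Provenance.PROTCID


class TestXtalMany:
    def test_screw_interface_selected(self):
        labels = build_xtalmany([record(op="2S", area=800.0, resolution=2.0)])
        assert len(labels) == 1
        assert labels[0].label == "XTAL"
        assert labels[0].provenance == Provenance.INFINITE

    @pytest.mark.parametrize("op,expected", [
        ("2S", 1), ("XT", 1), ("FT", 1), ("6S", 1),
        ("2", 0), ("AU", 0), ("4", 0),
    ])
    def test_only_infinite_operators(self, op, expected):
        assert len(build_xtalmany([record(op=op)])) == expected

    @pytest.mark.parametrize("area,expected", [
        (600.0, 1),   # at the bound: in
        (599.9, 0),   # trivially small contacts excluded
        (550.0, 0),
    ])
    def test_area_boundary(self, area, expected):
        assert len(build_xtalmany([record(area=area)])) == expected

    @pytest.mark.parametrize("resolution,expected", [(2.49, 1), (2.5, 0)])
    def test_resolution_strictly_better(self, resolution, expected):
        assert len(build_xtalmany([record(resolution=resolution)])) == expected

    def test_helical_biounit_excluded(self):
        assert build_xtalmany([record(biounit_symmetry="helical")]) == []

    def test_heteromeric_interfaces_excluded(self):
        assert build_xtalmany([record(seq_b=SEQ_FAR)]) == []

    def test_near_identical_partners_count_as_homomeric(self):
        assert len(build_xtalmany([record(seq_b=SEQ_B)])) == 1


class TestDatasetProperties:
    def test_disjoint_labels_from_one_run(self):
        records = [
            record("E1", protcid_cluster_id="c1",
                   n_crystal_forms_in_cluster=12, fraction_forms_present=0.9,
                   area=900.0, op="AU"),
            record("E2", seq_a=SEQ_FAR, seq_b=SEQ_FAR, op="2S", area=900.0),
        ]
        bio = {l.record.key for l in build_biomany(records)}
        xtal = {l.record.key for l in build_xtalmany(records)}
        assert bio and xtal and not bio & xtal

    def test_tightening_never_grows_output(self):
        rng = np.random.default_rng(0)
        records = [record(f"E{i}", seq_a=SEQ_FAR[:20] + "".join(
                       rng.choice(list("ACDEFGHIKL"), 13)),
                       seq_b=None, area=float(rng.uniform(300, 1500)),
                       resolution=float(rng.uniform(1.5, 3.0)))
                   for i in range(12)]
        for r in records:
            r.sequence_b = r.sequence_a
        n_loose = len(build_xtalmany(records, min_area=400.0))
        n_tight = len(build_xtalmany(records, min_area=800.0))
        assert n_tight <= n_loose

    def test_filters_commute(self):
        rng = np.random.default_rng(1)
        records = [record(f"E{i}", area=float(rng.uniform(300, 1200)),
                          resolution=float(rng.uniform(1.5, 3.5)))
                   for i in range(10)]
        by_area_first = [r for r in records if r.area >= 600.0]
        by_area_first = [r for r in by_area_first if r.resolution < 2.5]
        by_res_first = [r for r in records if r.resolution < 2.5]
        by_res_first = [r for r in by_res_first if r.area >= 600.0]
        assert by_area_first == by_res_first


class TestAreaCurve:
    def test_single_bin_probability_one(self):
        edges, probs = area_probability_curve([110, 120, 150], bin_width=100)
        assert probs.sum() == pytest.approx(1.0)
        assert probs[1] == pytest.approx(1.0)

    def test_normalization(self, rng):
        areas = rng.uniform(0, 2000, 500)
        _, probs = area_probability_curve(areas, 150.0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplication_invariance(self, rng):
        areas = list(rng.uniform(0, 1500, 200))
        _, p1 = area_probability_curve(areas, 100.0)
        _, p2 = area_probability_curve(areas + areas, 100.0)
        assert np.allclose(p1, p2)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            area_probability_curve([10.0, 20.0], 100.0, min_area=600.0)


class TestRecordIO:
    def test_tsv_roundtrip(self, tmp_path):
        records = [
            record("E1", protcid_cluster_id="c7",
                   n_crystal_forms_in_cluster=11, fraction_forms_present=0.82),
            record("E2", op="XT", resolution=None, nmr_matched=True),
        ]
        path = tmp_path / "records.tsv"
        write_records_tsv(records, path)
        back = read_records_tsv(path)
        assert [r.key for r in back] == [r.key for r in records]
        assert back[0].protcid_cluster_id == "c7"
        assert back[1].resolution is None
        assert back[1].nmr_matched is True
        assert back[1].operator_code == "XT"
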