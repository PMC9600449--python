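"""Alteration matching between primary and relapse biopsies: key
semantics, partition/symmetry invariants, driver-state logic, tallies."""

import numpy as np
import pytest

from lymphpanel.paired import (
    SampleAlterations,
    alteration_key,
    cohort_paired_summary,
    collect_hotspot_keys,
    compare_pair,
    loss_key,
    rearrangement_key,
    variant_key,
)

from conftest import make_variant


def myd88_l265p(sample_id):
    return make_variant(sample_id=sample_id, gene="MYD88", chrom="chr3",
                        pos=38182641, ref="T", alt="C", protein_change="L265P")


class TestAlterationKey:
    def test_identity_across_samples(self):
        a = make_variant(sample_id="P1", gene="ETV6", pos=100, ref="A", alt="T")
        b = make_variant(sample_id="P1-R", gene="ETV6", pos=100, ref="A", alt="T", vaf=0.9)
        assert variant_key(a) == variant_key(b)  # VAF and sample ignored

    def test_injective_in_position(self):
        a = make_variant(gene="MYD88", pos=38182641)
        b = make_variant(gene="MYD88", pos=38182650)
        assert variant_key(a) != variant_key(b)

    def test_type_separation(self):
        snv = make_variant(gene="CDKN2A", chrom="chr9", pos=21967100)
        assert variant_key(snv) != loss_key("CDKN2A")
        assert loss_key("CDKN2A") != rearrangement_key("CDKN2A")

    def test_dispatch(self):
        assert alteration_key(make_variant(gene="MYC", pos=5)) == (
            "MYC", "chr6", 5, "A", "G")
        with pytest.raises(TypeError):
            alteration_key("MYC")


class TestComparePair:
    def test_relapse_with_gain_and_losses(self):
        """A patient losing ETV6/BTG2/CD70 mutations and gaining MYC while
        the MYD88 hotspot persists: the driver profile stays stable."""
        primary = SampleAlterations(
            "LT_08",
            variants=[
                make_variant(sample_id="LT_08", gene="ETV6", pos=1),
                make_variant(sample_id="LT_08", gene="BTG2", pos=2),
                make_variant(sample_id="LT_08", gene="CD70", pos=3),
                myd88_l265p("LT_08"),
            ],
        )
        relapse = SampleAlterations(
            "LT_08-R",
            variants=[myd88_l265p("LT_08-R"),
                      make_variant(sample_id="LT_08-R", gene="MYC", pos=9)],
            losses={"CDKN2A"},
        )
        cmp = compare_pair("LT_08", primary, relapse)
        assert {k[0] for k in cmp.lost} == {"ETV6", "BTG2", "CD70"}
        assert {k[0] for k in cmp.gained} == {"MYC", "CDKN2A"}
        assert cmp.stable == {variant_key(myd88_l265p("LT_08"))}
        assert cmp.driver_state["MYD88-mut"] == "stable_present"
        assert cmp.driver_state["CDKN2A-loss"] == "gained"
        assert cmp.any_driver_stable

    def test_identical_sets_all_stable(self):
        s = SampleAlterations("P", variants=[make_variant(pos=i) for i in (1, 2, 3)],
                              losses={"CDKN2A"})
        cmp = compare_pair("P", s, s)
        assert not cmp.lost and not cmp.gained
        assert len(cmp.stable) == 4

    def test_same_gene_different_site_flagged(self):
        primary = SampleAlterations(
            "P", variants=[make_variant(gene="PIM1", pos=100,
                                        mutation_type="nonsynonymous")])
        relapse = SampleAlterations(
            "P-R", variants=[make_variant(gene="PIM1", pos=200,
                                          mutation_type="nonsynonymous")])
        cmp = compare_pair("P", primary, relapse)
        assert cmp.same_gene_different_site == {"PIM1"}
        assert len(cmp.lost) == 1 and len(cmp.gained) == 1

    def test_different_mutation_type_not_flagged(self):
        primary = SampleAlterations(
            "P", variants=[make_variant(gene="PIM1", pos=100,
                                        mutation_type="nonsynonymous")])
        relapse = SampleAlterations(
            "P-R", variants=[make_variant(gene="PIM1", pos=200,
                                          mutation_type="nonsense")])
        assert compare_pair("P", primary, relapse).same_gene_different_site == set()

    def test_gene_level_driver_state_without_hotspot(self):
        primary = SampleAlterations(
            "P", variants=[make_variant(gene="CD79B", pos=7, protein_change="A42V")])
        relapse = SampleAlterations("P-R")
        cmp = compare_pair("P", primary, relapse)
        assert cmp.driver_state["CD79B-mut"] == "lost"
        assert cmp.driver_state["MYD88-mut"] == "stable_absent"
        assert not cmp.any_driver_stable

    def test_patient_mismatch_rejected(self):
        s1 = SampleAlterations("A")
        s2 = SampleAlterations("B-R")
        with pytest.raises(ValueError, match="belong"):
            compare_pair("A", s1, s2, expected_patient={"A": "A", "B-R": "B"})

    def test_partition_and_symmetry_random(self):
        """Partition and swap-symmetry invariants over randomized pairs."""
        rng = np.random.default_rng(4)
        for _ in range(300):
            pool = [make_variant(gene=g, pos=int(p))
                    for g in ("PIM1", "MYC", "BTG1")
                    for p in rng.integers(1, 30, size=4)]
            pv = [v for v in pool if rng.random() < 0.5]
            rv = [v for v in pool if rng.random() < 0.5]
            p = SampleAlterations("P", variants=pv,
                                  losses={"CDKN2A"} if rng.random() < 0.3 else set())
            r = SampleAlterations("P-R", variants=rv,
                                  losses={"CDKN2A"} if rng.random() < 0.3 else set())
            fwd = compare_pair("P", p, r)
            bwd = compare_pair("P", r, p)
            union = p.keys() | r.keys()
            assert fwd.stable | fwd.lost | fwd.gained == union
            assert fwd.stable == bwd.stable
            assert fwd.lost == bwd.gained and fwd.gained == bwd.lost


class TestCohortSummary:
    def test_printed_tallies_arithmetic(self):
        """42 stable / 26 lost / 28 gained non-driver alterations give the
        fractions 44% / 27% / 29%."""
        stable = {("G", "chr1", i, "A", "T") for i in range(42)}
        lost = {("G", "chr1", 100 + i, "A", "T") for i in range(26)}
        gained = {("G", "chr1", 200 + i, "A", "T") for i in range(28)}
        from lymphpanel.paired import PairedComparison

        cmp = PairedComparison(
            patient_id="pool", stable=stable, lost=lost, gained=gained,
            same_gene_different_site=set(),
            driver_state={"MYD88-mut": "stable_absent",
                          "CD79B-mut": "stable_absent",
                          "CDKN2A-loss": "stable_absent"},
        )
        summary = cohort_paired_summary([cmp])
        assert (summary.n_stable, summary.n_lost, summary.n_gained) == (42, 26, 28)
        f = summary.fractions
        assert f[0] == pytest.approx(42 / 96)
        assert f[1] == pytest.approx(26 / 96)
        assert f[2] == pytest.approx(28 / 96)

    def test_identity_cohort(self):
        s = SampleAlterations("P", variants=[make_variant(pos=i) for i in (1, 2)])
        cmps = [compare_pair("P", s, s) for _ in range(5)]
        summary = cohort_paired_summary(cmps)
        assert summary.fractions == (1.0, 0.0, 0.0)

    def test_per_gene_discrepancy_ordering(self):
        p = SampleAlterations("P", variants=[
            make_variant(gene="MYC", pos=i) for i in range(10)])
        r = SampleAlterations("P-R", variants=[
            make_variant(gene="MYC", pos=i) for i in range(3)] + [
            make_variant(gene="PIM1", pos=i) for i in range(2)])
        summary = cohort_paired_summary([compare_pair("P", p, r)])
        assert list(summary.per_gene.gene) == ["MYC", "PIM1"]
        myc = summary.per_gene.iloc[0]
        assert (myc.n_lost, myc.n_gained) == (7, 0)

    def test_driver_filter_excludes_hotspots_and_loss(self):
        p = SampleAlterations("P", variants=[myd88_l265p("P"),
                                             make_variant(gene="BTG1", pos=4)],
                              losses={"CDKN2A"})
        r = SampleAlterations("P-R", variants=[myd88_l265p("P-R")], losses={"CDKN2A"})
        cmp = compare_pair("P", p, r)
        hot = collect_hotspot_keys([p, r])
        drivers = cohort_paired_summary([cmp], "drivers", hotspot_keys=hot)
        nondrivers = cohort_paired_summary([cmp], "non_drivers", hotspot_keys=hot)
        assert drivers.n_stable == 2 and drivers.n_lost == 0
        assert nondrivers.n_stable == 0 and nondrivers.n_lost == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_paired_summary([])
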