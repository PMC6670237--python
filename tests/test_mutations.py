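"""Variant filtering, driver/hotspot annotation, catalogs, enrichment, refitting."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_variant_row, variant_frame
from mammotype import contexts, synthetic
from mammotype.errors import (
    EmptyCatalogError,
    InvalidInputError,
    InvalidReferenceError,
    MalformedRecordError,
)
from mammotype.mutations import (
    annotate_drivers,
    build_catalog,
    context_enrichment_test,
    filter_variants,
    genome_flank_proportion,
    hotspot_lookup,
    mutated_tumor_percent,
    refit_signatures,
    spectrum_summary,
    validate_signature_matrix,
)


class TestFilterVariants:
    @pytest.mark.parametrize(
        "overrides,rule",
        [
            ({"alt_depth": 9, "total_depth": 100, "alt_forward": 5, "alt_reverse": 4}, "depth"),
            ({"alt_depth": 10, "total_depth": 250, "alt_forward": 5, "alt_reverse": 5}, "vaf"),
            ({"alt_depth": 12, "total_depth": 100, "alt_forward": 12, "alt_reverse": 0}, "strand"),
            ({"caller_pass": False}, "caller_pass"),
        ],
    )
    def test_single_rule_failures(self, overrides, rule):
        df = variant_frame([make_variant_row(**overrides)])
        retained, removed = filter_variants(df)
        assert len(retained) == 0
        assert removed[rule] == 1
        assert sum(removed.values()) == 1

    def test_passing_record_retained(self):
        retained, removed = filter_variants(variant_frame([make_variant_row()]))
        assert len(retained) == 1 and sum(removed.values()) == 0

    def test_normal_and_snp_site_rules(self):
        df = variant_frame([
            make_variant_row(pos=100),
            make_variant_row(pos=200),
            make_variant_row(pos=300),
        ])
        retained, removed = filter_variants(df, {("chr1", 100)}, {("chr1", 200)})
        assert list(retained["pos"]) == [300]
        assert removed["normal"] == 1 and removed["snp"] == 1

    def test_counts_conserve_input(self, variant_cohort):
        records, snps = variant_cohort
        retained, removed = filter_variants(records, snp_sites=snps)
        assert len(retained) + sum(removed.values()) == len(records)

    def test_planted_failures_attributed_exactly(self, variant_cohort):
        records, snps = variant_cohort
        retained, removed = filter_variants(records, snp_sites=snps)
        planted = records["planted_fail_rule"]
        # every planted record removed, every passing record retained
        assert set(retained.index) == set(records.index[planted == ""])
        for rule, n in planted.value_counts().items():
            if rule:
                assert removed[rule] == n

    def test_zero_depth_rejected(self):
        df = variant_frame([make_variant_row(total_depth=0, alt_depth=0,
                                             alt_forward=0, alt_reverse=0)])
        with pytest.raises(MalformedRecordError):
            filter_variants(df)

    def test_strand_sum_invariant_enforced(self):
        df = variant_frame([make_variant_row(alt_forward=3, alt_reverse=3)])
        with pytest.raises(MalformedRecordError, match="alt_forward"):
            filter_variants(df)


class TestAnnotateDrivers:
    def test_impact_and_census_combinations(self):
        df = variant_frame([
            make_variant_row(gene="Trp53", impact="MODERATE"),
            make_variant_row(gene="Notacensus", impact="HIGH"),
            make_variant_row(gene="Trp53", impact="LOW"),
        ])
        out, per_tumor = annotate_drivers(df, {"Trp53", "Kras"})
        assert list(out["driver"]) == [True, False, False]
        assert per_tumor["t1"] == 1

    def test_empty_census_warns(self):
        df = variant_frame([make_variant_row()])
        with pytest.warns(UserWarning, match="census"):
            out, _ = annotate_drivers(df, set())
        assert not out["driver"].any()


class TestHotspotLookup:
    def test_known_hotspots_hit(self):
        df = variant_frame([
            make_variant_row(gene="Kras", aa_change="Gly12Cys"),
            make_variant_row(gene="Pik3ca", aa_change="His1047Arg"),
        ])
        ortholog = {("Kras", 12): ("KRAS", 12), ("Pik3ca", 1047): ("PIK3CA", 1047)}
        hotspots = {("KRAS", 12, "Gly12Cys"), ("PIK3CA", 1047, "His1047Arg")}
        hits, unmapped = hotspot_lookup(df, ortholog, hotspots)
        assert set(hits["human_gene"]) == {"KRAS", "PIK3CA"}
        assert unmapped == []

    def test_unmapped_position_reported_not_error(self):
        df = variant_frame([make_variant_row(gene="Kras", aa_change="Gly12Cys")])
        hits, unmapped = hotspot_lookup(df, {}, set())
        assert len(hits) == 0 and unmapped == [("Kras", 12)]

    def test_malformed_aa_change_skipped_with_warning(self):
        df = variant_frame([make_variant_row(gene="Kras", aa_change="p.G12C")])
        with pytest.warns(UserWarning, match="malformed"):
            hits, unmapped = hotspot_lookup(df, {("Kras", 12): ("KRAS", 12)}, set())
        assert len(hits) == 0 and unmapped == []

    def test_offset_ortholog_mapping(self):
        df = variant_frame([make_variant_row(gene="Trp53", aa_change="His211Pro")])
        ortholog = {("Trp53", 211): ("TP53", 214)}
        hits, _ = hotspot_lookup(df, ortholog, {("TP53", 214, "His214Pro")})
        assert hits.iloc[0]["human_aa_change"] == "His214Pro"


class TestBuildCatalog:
    def test_purine_reference_collapsed(self):
        # A>T at context CAT is recorded as T>A at context ATG
        df = variant_frame([make_variant_row(ref_allele="A", alt_allele="T",
                                             trinucleotide="CAT")])
        catalog, n_non_snv = build_catalog(df)
        assert catalog.loc["A[T>A]G", "t1"] == 1
        assert catalog["t1"].sum() == 1 and n_non_snv == 0

    def test_total_conserved(self, variant_cohort):
        records, _ = variant_cohort
        catalog, n_non_snv = build_catalog(records)
        assert catalog.to_numpy().sum() + n_non_snv == len(records)

    def test_matches_dictionary_count_oracle(self, rng):
        rows = []
        tally: dict[str, int] = {}
        for i in range(200):
            label = contexts.CONTEXT_CLASSES[rng.integers(0, 96)]
            five, ref, alt, three = contexts.parse_class(label)
            tri = five + ref + three
            if rng.random() < 0.5:
                ref, alt, tri = (contexts.revcomp(ref), contexts.revcomp(alt),
                                 contexts.revcomp(tri))
            rows.append(make_variant_row(pos=i, ref_allele=ref, alt_allele=alt,
                                         trinucleotide=tri))
            tally[label] = tally.get(label, 0) + 1
        catalog, _ = build_catalog(variant_frame(rows))
        for label in contexts.CONTEXT_CLASSES:
            assert catalog.loc[label, "t1"] == tally.get(label, 0)

    def test_strand_mirror_idempotence(self, variant_cohort):
        records, _ = variant_cohort
        snvs = records[records["ref_allele"].str.len() == 1].head(300).copy()
        mirrored = snvs.copy()
        mirrored["ref_allele"] = [contexts.revcomp(b) for b in snvs["ref_allele"]]
        mirrored["alt_allele"] = [contexts.revcomp(b) for b in snvs["alt_allele"]]
        mirrored["trinucleotide"] = [contexts.revcomp(t) for t in snvs["trinucleotide"]]
        c1, _ = build_catalog(snvs)
        c2, _ = build_catalog(mirrored)
        assert c1.equals(c2)

    def test_inconsistent_trinucleotide_rejected(self):
        df = variant_frame([make_variant_row(trinucleotide="AGA")])
        with pytest.raises(MalformedRecordError):
            build_catalog(df)


class TestSpectrum:
    def test_single_class_catalog(self):
        counts = pd.Series(0, index=list(contexts.CONTEXT_CLASSES))
        counts["A[T>A]G"] = 17
        props = spectrum_summary(counts)
        assert props["T>A"] == 1.0

    def test_proportions_sum_to_one(self, rng):
        counts = pd.Series(rng.integers(0, 40, 96), index=list(contexts.CONTEXT_CLASSES))
        assert spectrum_summary(counts).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_catalog_rejected(self):
        counts = pd.Series(0, index=list(contexts.CONTEXT_CLASSES))
        with pytest.raises(EmptyCatalogError):
            spectrum_summary(counts)


def _catalogs_with_tg_fraction(fraction, n_tumors, n_muts, rng):
    """Catalogs of T>A mutations with a fixed 3'-G fraction among T mutations."""
    catalogs = pd.DataFrame(0, index=list(contexts.CONTEXT_CLASSES),
                            columns=[f"t{i}" for i in range(n_tumors)])
    for t in catalogs.columns:
        n_tg = int(round(fraction * n_muts))
        catalogs.loc["A[T>A]G", t] = n_tg
        catalogs.loc["A[T>A]C", t] = n_muts - n_tg
    return catalogs


class TestContextEnrichment:
    def test_zero_differences_give_p_one(self, rng):
        freqs = pd.Series(1.0 / 32, index=list(contexts.PYRIMIDINE_CONTEXTS_32))
        # genome proportion of 3'G given T is 0.25; build catalogs matching it
        catalogs = _catalogs_with_tg_fraction(0.25, 8, 100, rng)
        with pytest.warns(UserWarning):
            res = context_enrichment_test(catalogs, freqs, "T", "G", "3prime")
        assert res["p_value"] == 1.0

    def test_planted_enrichment_detected(self, rng):
        freqs = pd.Series(1.0 / 32, index=list(contexts.PYRIMIDINE_CONTEXTS_32))
        catalogs = _catalogs_with_tg_fraction(0.25 + 0.3, 18, 200, rng)
        res = context_enrichment_test(catalogs, freqs, "T", "G", "3prime")
        assert res["direction"] == "enriched"
        assert res["p_value"] < 1e-3

    def test_depletion_flips_direction(self, rng):
        freqs = pd.Series(1.0 / 32, index=list(contexts.PYRIMIDINE_CONTEXTS_32))
        catalogs = _catalogs_with_tg_fraction(0.05, 10, 200, rng)
        res = context_enrichment_test(catalogs, freqs, "T", "G", "3prime")
        assert res["direction"] == "depleted"

    def test_genome_conditional_proportion(self):
        freqs = synthetic.generate_trinuc_freqs(seed=3, tg_boost=0.2)
        p = genome_flank_proportion(freqs, "T", "G", "3prime")
        t_contexts = [c for c in contexts.PYRIMIDINE_CONTEXTS_32 if c[1] == "T"]
        manual = sum(freqs[c] for c in t_contexts if c[2] == "G") / sum(
            freqs[c] for c in t_contexts
        )
        assert p == pytest.approx(manual)

    def test_too_few_tumors_rejected(self, rng):
        freqs = pd.Series(1.0 / 32, index=list(contexts.PYRIMIDINE_CONTEXTS_32))
        catalogs = _catalogs_with_tg_fraction(0.5, 4, 50, rng)
        with pytest.raises(InvalidInputError):
            context_enrichment_test(catalogs, freqs, "T", "G")


class TestRefitSignatures:
    def test_single_source_recovery(self, reference_signatures, rng):
        truth = reference_signatures.columns[1]
        draws = rng.multinomial(1000, reference_signatures[truth].to_numpy())
        exposure = refit_signatures(
            pd.Series(draws, index=reference_signatures.index), reference_signatures
        )
        assert exposure.weights[truth] >= 0.95
        assert (exposure.weights.drop(truth) == 0).all()

    def test_noiseless_mixture_recovery(self, reference_signatures):
        a, b = reference_signatures.columns[:2]
        mix = 0.6 * reference_signatures[a] + 0.4 * reference_signatures[b]
        exposure = refit_signatures(mix * 1000, reference_signatures)
        assert exposure.weights[a] == pytest.approx(0.6, abs=0.02)
        assert exposure.weights[b] == pytest.approx(0.4, abs=0.02)

    def test_weights_nonnegative_and_bounded(self, variant_cohort, reference_signatures):
        records, _ = variant_cohort
        catalog, _ = build_catalog(records)
        for tumor in catalog.columns[:4]:
            exp = refit_signatures(catalog[tumor], reference_signatures, tumor_id=tumor)
            assert (exp.weights >= 0).all()
            assert exp.weights.sum() <= 1 + 1e-9
            assert exp.unexplained == pytest.approx(1 - exp.weights.sum(), abs=1e-9)

    def test_cutoff_zeroes_small_weights(self, reference_signatures):
        a, b = reference_signatures.columns[:2]
        mix = 0.97 * reference_signatures[a] + 0.03 * reference_signatures[b]
        exposure = refit_signatures(mix * 5000, reference_signatures, weight_cutoff=0.06)
        assert exposure.weights[b] == 0.0

    def test_invalid_reference_rejected(self, reference_signatures):
        bad = reference_signatures * 2.0
        with pytest.raises(InvalidReferenceError):
            validate_signature_matrix(bad)

    def test_small_catalog_warns(self, reference_signatures):
        counts = pd.Series(0, index=reference_signatures.index)
        counts.iloc[0] = 30
        with pytest.warns(UserWarning, match="unstable"):
            refit_signatures(counts, reference_signatures)


def test_mutated_tumor_percent_rounds_to_integer():
    df = variant_frame([make_variant_row(gene="Pik3ca", tumor_id="t7")])
    k, pct = mutated_tumor_percent(df, "Pik3ca", n_tumors=18)
    assert (k, pct) == (1, 6)
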