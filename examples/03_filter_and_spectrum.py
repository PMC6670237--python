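"""Filter candidate somatic variants and characterize the mutational spectrum.

Generates a variant table in which 10% of records are planted to fail
exactly one hard filter, applies the filters (caller PASS, alt depth >= 10,
VAF >= 0.05, both strands, SNP sites), builds 96-context catalogs and tests
3'-flank enrichment against a genome trinucleotide background.
"""

from mammotype import mutations, synthetic

config = synthetic.SyntheticCohortConfig(seed=5, n_mutations_per_tumor=400)
reference = synthetic.generate_signature_matrix(n_signatures=3, seed=5)
records, snp_sites = synthetic.generate_variant_table(config, reference)

retained, removed = mutations.filter_variants(records, snp_sites=snp_sites)
print(f"candidate variants: {len(records)}; retained after filtering: {len(retained)}")
for rule, n in removed.items():
    if n:
        print(f"  removed by {rule}: {n}")

catalogs, n_non_snv = mutations.build_catalog(retained)
pooled = mutations.spectrum_summary(catalogs.sum(axis=1))
print("pooled substitution spectrum (fractions of all SNVs):")
print(pooled.round(3).to_string())

genome = synthetic.generate_trinuc_freqs(seed=5)
enrich = mutations.context_enrichment_test(catalogs, genome, "T", "G", "3prime")
print(f"T>N mutations with 3' G: observed mean fraction "
      f"{enrich['observed_fractions'].mean():.3f} vs genome NTG proportion "
      f"{enrich['genome_proportion']:.3f} -> {enrich['direction']}, "
      f"p = {enrich['p_value']:.3g} (signed-rank across tumors)")
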