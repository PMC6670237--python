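"""Somatic-mutation pipeline: filtering, driver/hotspot annotation, spectra, refitting.

The pipeline starts from a candidate-variant table (MAF-like; one row per
candidate SNV with per-strand alt depths, caller flag, impact class and
trinucleotide context) and applies, in order:

1. hard filters — caller PASS, alt-allele depth >= 10, VAF >= 0.05, alt
   support on both strands, absence from matched-normal and known-SNP sites;
2. candidate-driver annotation — moderate/high impact in a cancer gene
   census gene;
3. hotspot lookup — mouse amino-acid changes mapped through an ortholog
   position table and queried against a human hotspot set;
4. 96-context catalog construction (pyrimidine-strand collapsed), spectrum
   summaries and flank-enrichment tests against genome background; and
5. non-negative signature refitting against a reference signature matrix by
   forward-selection coordinate descent with a reporting cutoff.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import contexts
from .errors import (
    EmptyCatalogError,
    InvalidInputError,
    InvalidReferenceError,
    MalformedRecordError,
)
from .stats import GroupComparison, wilcoxon_signed_rank

__all__ = [
    "VARIANT_COLUMNS",
    "FILTER_RULES",
    "ExposureVector",
    "validate_variant_table",
    "filter_variants",
    "annotate_drivers",
    "hotspot_lookup",
    "build_catalog",
    "spectrum_summary",
    "context_enrichment_test",
    "refit_signatures",
    "validate_signature_matrix",
    "genome_flank_proportion",
    "mutated_tumor_percent",
]

#: required columns of a candidate-variant table (MAF-like TSV)
VARIANT_COLUMNS: tuple[str, ...] = (
    "tumor_id", "chrom", "pos", "ref_allele", "alt_allele",
    "total_depth", "alt_depth", "alt_forward", "alt_reverse",
    "caller_pass", "gene", "impact", "aa_change", "trinucleotide",
)

#: filter rules in fixed attribution order
FILTER_RULES: tuple[str, ...] = ("caller_pass", "depth", "vaf", "strand", "normal", "snp")

IMPACT_CLASSES = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})

_AA_CHANGE_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def validate_variant_table(records: pd.DataFrame) -> None:
    """Check the VariantRecord invariants; raise MalformedRecordError on violation."""
    missing = set(VARIANT_COLUMNS) - set(records.columns)
    if missing:
        raise MalformedRecordError(f"variant table missing columns: {sorted(missing)}")
    if len(records) == 0:
        return
    if (records["total_depth"] <= 0).any():
        bad = records.index[records["total_depth"] <= 0].tolist()[:5]
        raise MalformedRecordError(f"total_depth must be positive (rows {bad})")
    if (records["alt_forward"] + records["alt_reverse"] != records["alt_depth"]).any():
        raise MalformedRecordError("alt_forward + alt_reverse must equal alt_depth")
    if (records["alt_depth"] > records["total_depth"]).any():
        raise MalformedRecordError("alt_depth exceeds total_depth")
    snv = records["ref_allele"].str.len().eq(1) & records["alt_allele"].str.len().eq(1)
    mid = records.loc[snv, "trinucleotide"].str[1]
    if (mid != records.loc[snv, "ref_allele"]).any():
        raise MalformedRecordError("trinucleotide middle base does not match ref_allele")


def filter_variants(
    records: pd.DataFrame,
    normal_sites: Iterable[tuple] = (),
    snp_sites: Iterable[tuple] = (),
    min_depth: int = 10,
    min_vaf: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the somatic hard filters; return (retained records, per-rule removal counts).

    A record is retained iff it passed the caller, has alt-allele depth >=
    ``min_depth``, VAF >= ``min_vaf``, alt support on both strands, and its
    (chrom, pos) site is in neither the matched-normal nor the known-SNP
    site set.  Removal is attributed to the first failing rule in the fixed
    order pass -> depth -> VAF -> strand -> normal -> SNP, so that
    retained + per-rule removals always sums to the input count.
    """
    validate_variant_table(records)
    normal_sites = set(map(tuple, normal_sites))
    snp_sites = set(map(tuple, snp_sites))
    sites = list(zip(records["chrom"], records["pos"]))
    vaf = records["alt_depth"] / records["total_depth"]
    fails = {
        "caller_pass": ~records["caller_pass"].astype(bool),
        "depth": records["alt_depth"] < min_depth,
        "vaf": vaf < min_vaf,
        "strand": (records["alt_forward"] < 1) | (records["alt_reverse"] < 1),
        "normal": pd.Series([s in normal_sites for s in sites], index=records.index),
        "snp": pd.Series([s in snp_sites for s in sites], index=records.index),
    }
    removal_counts = dict.fromkeys(FILTER_RULES, 0)
    attributed = pd.Series(False, index=records.index)
    for rule in FILTER_RULES:
        hit = fails[rule] & ~attributed
        removal_counts[rule] = int(hit.sum())
        attributed |= hit
    retained = records.loc[~attributed].copy()
    assert len(retained) + sum(removal_counts.values()) == len(records)
    return retained, removal_counts


def annotate_drivers(
    records: pd.DataFrame, census_genes: Iterable[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag candidate driver mutations: moderate/high impact in a census gene.

    Returns the table with a boolean ``driver`` column and a per-tumor
    count of distinct driver genes carrying mutations.
    """
    census = set(census_genes)
    if not census:
        warnings.warn("empty cancer gene census: zero driver calls")
    out = records.copy()
    out["driver"] = out["impact"].isin({"HIGH", "MODERATE"}) & out["gene"].isin(census)
    per_tumor = (
        out.loc[out["driver"]].groupby("tumor_id")["gene"].nunique()
        .reindex(out["tumor_id"].unique(), fill_value=0)
    )
    return out, per_tumor


def hotspot_lookup(
    records: pd.DataFrame,
    ortholog_map: Mapping[tuple[str, int], tuple[str, int]],
    hotspot_table: set[tuple[str, int, str]],
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Query mouse amino-acid changes against a human hotspot set.

    ``aa_change`` is parsed as three-letter RefPosAlt (e.g. ``Gly12Cys``);
    the (mouse gene, position) is mapped through ``ortholog_map`` to a
    (human gene, position), and a hit is recorded when
    (human gene, human position, Ref<human pos>Alt) is in ``hotspot_table``.
    Positions absent from the map are reported as unmapped, not errors;
    malformed aa_change strings are skipped with a warning.
    """
    hits = []
    unmapped: list[tuple[str, int]] = []
    for _, rec in records.iterrows():
        aa = rec["aa_change"]
        if not aa:
            continue
        m = _AA_CHANGE_RE.match(str(aa))
        if m is None:
            warnings.warn(f"malformed aa_change {aa!r} for {rec['gene']}; skipped")
            continue
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        key = (rec["gene"], pos)
        if key not in ortholog_map:
            unmapped.append(key)
            continue
        hgene, hpos = ortholog_map[key]
        if (hgene, hpos, f"{ref3}{hpos}{alt3}") in hotspot_table:
            hits.append({
                "tumor_id": rec["tumor_id"], "gene": rec["gene"], "aa_change": aa,
                "human_gene": hgene, "human_aa_change": f"{ref3}{hpos}{alt3}",
            })
    hits_df = pd.DataFrame(hits, columns=["tumor_id", "gene", "aa_change",
                                          "human_gene", "human_aa_change"])
    return hits_df, unmapped


def build_catalog(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Accumulate per-tumor 96-context catalogs from SNV records.

    Purine-reference records are collapsed to the pyrimidine strand (the
    context is reverse-complemented with them).  Non-SNV records (multi-base
    ref or alt) are excluded and counted.  Returns (96 x tumors count
    DataFrame indexed by class label, number of non-SNVs excluded).
    """
    validate_variant_table(records)
    tumors = list(dict.fromkeys(records["tumor_id"]))
    counts = pd.DataFrame(0, index=list(contexts.CONTEXT_CLASSES), columns=tumors, dtype=int)
    is_snv = records["ref_allele"].str.len().eq(1) & records["alt_allele"].str.len().eq(1)
    n_non_snv = int((~is_snv).sum())
    snvs = records.loc[is_snv]
    labels = [
        contexts.classify_snv(r, a, t)
        for r, a, t in zip(snvs["ref_allele"], snvs["alt_allele"], snvs["trinucleotide"])
    ]
    for tumor, label in zip(snvs["tumor_id"], labels):
        counts.at[label, tumor] += 1
    return counts, n_non_snv


def spectrum_summary(catalog: pd.Series) -> pd.Series:
    """Proportions of the six substitution types for one catalog (96-count vector)."""
    catalog = catalog.reindex(list(contexts.CONTEXT_CLASSES))
    if catalog.isna().any():
        raise InvalidInputError("catalog must be indexed by the 96 context classes")
    total = catalog.sum()
    if total <= 0:
        raise EmptyCatalogError("catalog has zero total count")
    sub_of = pd.Series({c: c[2:5] for c in contexts.CONTEXT_CLASSES})
    props = catalog.groupby(sub_of).sum() / total
    return props.reindex(list(contexts.SUBSTITUTION_TYPES))


def genome_flank_proportion(
    genome_freqs: pd.Series,
    mutated_base: Literal["C", "T"],
    flank_base: str,
    side: Literal["5prime", "3prime"],
) -> float:
    """Conditional genome proportion of ``flank_base`` at ``side`` given the
    central pyrimidine, from a 32-context trinucleotide frequency table.

    E.g. for (T, G, 3prime): freq(NTG) / freq(NTN), the genome background
    against which 3'-flank enrichment of thymine mutations is tested.
    """
    freqs = genome_freqs.reindex(list(contexts.PYRIMIDINE_CONTEXTS_32))
    if freqs.isna().any() or (freqs < 0).any():
        raise InvalidInputError("genome_freqs must cover the 32 pyrimidine contexts, >= 0")
    if not np.isclose(freqs.sum(), 1.0, atol=1e-6):
        raise InvalidInputError("genome trinucleotide frequencies must sum to 1")
    center = freqs[[c for c in freqs.index if c[1] == mutated_base]]
    flank_pos = 0 if side == "5prime" else 2
    matching = center[[c for c in center.index if c[flank_pos] == flank_base]]
    return float(matching.sum() / center.sum())


def context_enrichment_test(
    catalogs: pd.DataFrame,
    genome_freqs: pd.Series,
    mutated_base: Literal["C", "T"],
    flank_base: str,
    side: Literal["5prime", "3prime"] = "3prime",
) -> dict:
    """Test whether mutations of ``mutated_base`` are enriched for a flanking
    base relative to the genome's trinucleotide composition.

    Per tumor, the observed fraction of ``mutated_base`` mutations whose
    ``side`` flank equals ``flank_base`` is compared to the genome's
    conditional proportion of that flank (e.g. the proportion of thymines
    in an NTG context for 3'-G enrichment of T>N mutations); the per-tumor
    differences are tested with a two-tailed one-sample Wilcoxon signed-rank
    test.  Tumors with no mutations of the base are excluded with a warning.
    """
    if catalogs.shape[1] < 6:
        raise InvalidInputError("context enrichment test requires >= 6 tumors")
    expected = genome_flank_proportion(genome_freqs, mutated_base, flank_base, side)
    flank_pos = 0 if side == "5prime" else 6  # position within e.g. "A[C>A]G"
    rows_base = [c for c in catalogs.index if c[2] == mutated_base]
    rows_match = [c for c in rows_base if c[flank_pos] == flank_base]
    totals = catalogs.loc[rows_base].sum(axis=0)
    usable = totals > 0
    if (~usable).any():
        warnings.warn(
            f"{int((~usable).sum())} tumor(s) with no {mutated_base} mutations excluded"
        )
    observed = catalogs.loc[rows_match, usable].sum(axis=0) / totals[usable]
    diffs = observed - expected
    comparison = wilcoxon_signed_rank(diffs.to_numpy())
    return {
        "observed_fractions": observed,
        "genome_proportion": expected,
        "mean_difference": float(diffs.mean()),
        "direction": "enriched" if diffs.mean() > 0 else "depleted",
        "comparison": comparison,
        "p_value": comparison.p_value,
    }


def validate_signature_matrix(reference: pd.DataFrame) -> None:
    """Check a reference signature matrix: 96 rows, columns summing to 1, >= 0."""
    if set(reference.index) != set(contexts.CONTEXT_CLASSES):
        raise InvalidReferenceError("signature matrix must be indexed by the 96 classes")
    if (reference.to_numpy() < 0).any():
        raise InvalidReferenceError("signature probabilities must be non-negative")
    colsums = reference.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        bad = colsums[~np.isclose(colsums, 1.0, atol=1e-6)].index.tolist()
        raise InvalidReferenceError(f"signature columns must sum to 1: {bad}")


@dataclass(frozen=True)
class ExposureVector:
    """Refitted signature exposures for one tumor."""

    tumor_id: str
    weights: pd.Series  # per reference signature, >= 0, sum <= 1
    unexplained: float  # 1 - sum(weights)
    residual_sse: float

    def __post_init__(self) -> None:
        if (self.weights < 0).any() or self.weights.sum() > 1 + 1e-9:
            raise ValueError("weights must be non-negative with sum <= 1")


def _coordinate_descent(
    m: np.ndarray, P: np.ndarray, support: np.ndarray, tol: float, max_iter: int = 2000
) -> np.ndarray:
    """Greedy coordinate descent for min ||m - P w||^2, w >= 0, sum(w) <= 1.

    At each step the single signature weight (within ``support``) whose
    1-D-optimal update most reduces the SSE is updated; stops when the
    relative SSE improvement falls below ``tol``.
    """
    n_sig = P.shape[1]
    w = np.zeros(n_sig)
    sq_norms = np.einsum("ij,ij->j", P, P)
    resid = m.copy()
    sse = float(resid @ resid)
    for _ in range(max_iter):
        best_j, best_new, best_sse = -1, 0.0, sse
        head = 1.0 - w.sum()
        for j in np.flatnonzero(support):
            if sq_norms[j] == 0:
                continue
            step = (P[:, j] @ resid) / sq_norms[j]
            new_wj = np.clip(w[j] + step, 0.0, w[j] + head)
            delta = new_wj - w[j]
            if delta == 0.0:
                continue
            new_sse = sse - 2 * delta * (P[:, j] @ resid) + delta * delta * sq_norms[j]
            if new_sse < best_sse:
                best_j, best_new, best_sse = j, new_wj, new_sse
        if best_j < 0 or (sse - best_sse) < tol * max(sse, 1e-30):
            break
        resid = resid - (best_new - w[best_j]) * P[:, best_j]
        w[best_j] = best_new
        sse = float(resid @ resid)
    return w


def refit_signatures(
    catalog: pd.Series,
    reference: pd.DataFrame,
    weight_cutoff: float = 0.06,
    tol: float = 1e-3,
    tumor_id: str = "",
) -> ExposureVector:
    """Express a 96-context catalog as a non-negative mixture of reference
    signatures by forward-selection coordinate descent.

    The catalog is normalized to a probability vector; weights are grown
    greedily (non-negative, summing to at most 1) until the relative
    reduction in sum-of-squared reconstruction error falls below ``tol``.
    Weights below ``weight_cutoff`` (default 0.06, the conventional
    refitting cutoff) are zeroed and the fit is re-run restricted to the
    surviving signatures.  ``unexplained`` is 1 minus the total weight.
    """
    validate_signature_matrix(reference)
    catalog = catalog.reindex(reference.index)
    if catalog.isna().any() or (catalog < 0).any():
        raise InvalidInputError("catalog must be non-negative over the 96 classes")
    total = catalog.sum()
    if total <= 0:
        raise EmptyCatalogError("cannot refit an empty catalog")
    if total < 50:
        warnings.warn(f"catalog total {int(total)} < 50: refitting will be unstable")
    m = (catalog / total).to_numpy(dtype=float)
    P = reference.to_numpy(dtype=float)
    n_sig = P.shape[1]
    w = _coordinate_descent(m, P, np.ones(n_sig, dtype=bool), tol)
    keep = w >= weight_cutoff
    if keep.sum() < (w > 0).sum():
        w = _coordinate_descent(m, P, keep, tol * 1e-3)
        w[~keep] = 0.0
    resid = m - P @ w
    weights = pd.Series(w, index=reference.columns, name=tumor_id or None)
    return ExposureVector(
        tumor_id=tumor_id,
        weights=weights,
        unexplained=float(max(0.0, 1.0 - w.sum())),
        residual_sse=float(resid @ resid),
    )


def mutated_tumor_percent(records: pd.DataFrame, gene: str, n_tumors: int) -> tuple[int, int]:
    """Cohort mutation rate for one gene: (tumors mutated, integer percent).

    E.g. one Pik3ca-mutated tumor in a cohort of 18 gives (1, 6).
    """
    if n_tumors <= 0:
        raise InvalidInputError("n_tumors must be positive")
    k = records.loc[records["gene"] == gene, "tumor_id"].nunique()
    return int(k), int(round(100.0 * k / n_tumors))
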