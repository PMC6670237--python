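"""Synthetic cohort generator with known ground truth.

Emulates every input the pipeline consumes, shaped like the MPA/DMBA mouse
mammary tumor study design: an 18-tumor cohort spanning 9 transcriptomic
subtypes (2 tumors each by default), candidate somatic-variant tables with
a configurable fraction of records planted to fail exactly one hard
filter, a reference mutational-signature matrix with per-tumor mixture
weights, gene-level CNA profiles with planted driver events and a planted
near-identical tumor pair, and a genome trinucleotide background table.

Everything is driven by one global seed through independent spawned
streams, so identical configs give byte-identical outputs and the
generators stay decoupled.  All planted events (subtype labels, filter
failures, signature weights, driver CNAs, the similar pair) are returned
as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import contexts
from .errors import InvalidConfigError

__all__ = [
    "SyntheticCohortConfig",
    "generate_expression_cohort",
    "generate_variant_table",
    "generate_cna_profiles",
    "generate_signature_matrix",
    "generate_census",
    "generate_trinuc_freqs",
]

_AA3 = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-shaped cohort configuration.

    Defaults mirror the modelled study: 9 subtypes x 2 tumors, 589
    mutations per tumor (the cohort mean), ~58x sequencing depth, and a
    CNA event rate of 0.065 (about 1300 aberrant genes out of 20k).
    ``signature_weights`` is one mixture over the reference signatures
    applied to every tumor, or one mixture per tumor; ``None`` means
    uniform over the supplied reference signatures.
    """

    n_subtypes: int = 9
    n_genes: int = 1000
    n_samples_per_subtype: int = 2
    noise_sd: float = 0.5
    seed: int = 0
    n_mutations_per_tumor: int = 589
    signature_weights: tuple | None = None
    filter_fail_fraction: float = 0.1
    n_cna_genes: int = 2000
    cna_event_rate: float = 0.065
    mean_depth: float = 58.0

    def __post_init__(self) -> None:
        if self.n_subtypes < 2:
            raise InvalidConfigError("n_subtypes must be >= 2")
        if self.n_genes < 10:
            raise InvalidConfigError("n_genes must be >= 10")
        for name in ("n_samples_per_subtype", "n_mutations_per_tumor", "n_cna_genes"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if not (0.0 <= self.filter_fail_fraction <= 1.0):
            raise InvalidConfigError("filter_fail_fraction must be in [0, 1]")
        if not (0.0 <= self.cna_event_rate <= 1.0):
            raise InvalidConfigError("cna_event_rate must be in [0, 1]")

    @property
    def n_tumors(self) -> int:
        return self.n_subtypes * self.n_samples_per_subtype

    def tumor_ids(self) -> list[str]:
        return [f"tumor_{i + 1:02d}" for i in range(self.n_tumors)]

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent per-generator random streams spawned from the one seed."""
        kinds = ("expression", "variants", "cna", "signatures", "background")
        seqs = np.random.SeedSequence(self.seed).spawn(len(kinds))
        return {k: np.random.default_rng(s) for k, s in zip(kinds, seqs)}


def _subtype_names(n: int) -> list[str]:
    return [f"subtype_{i + 1:02d}" for i in range(n)]


def generate_expression_cohort(
    config: SyntheticCohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Centroid-plus-Gaussian-noise expression cohort with known labels.

    Centroids are random block-structured vectors: an i.i.d. N(0,1) draw
    per gene plus a +2.5 shift on that subtype's own gene block, which
    keeps pairwise centroid Spearman correlations far below 0.9.  Each
    sample is its subtype centroid plus i.i.d. N(0, noise_sd) noise.

    Returns (genes x samples matrix, genes x subtypes centroids,
    sample -> subtype label Series).
    """
    rng = config.streams()["expression"]
    genes = [f"gene_{i + 1:04d}" for i in range(config.n_genes)]
    subtypes = _subtype_names(config.n_subtypes)
    blocks = np.array_split(np.arange(config.n_genes), config.n_subtypes)
    cent = rng.standard_normal((config.n_genes, config.n_subtypes))
    for k, block in enumerate(blocks):
        cent[block, k] += 2.5
    centroids = pd.DataFrame(cent, index=genes, columns=subtypes)
    rho = centroids.corr(method="spearman").to_numpy()
    np.fill_diagonal(rho, 0.0)
    if np.abs(rho).max() >= 0.9:  # pragma: no cover - guaranteed by construction
        raise InvalidConfigError("centroids are not distinct (|rho| >= 0.9)")

    labels = {}
    cols = {}
    tumor_ids = config.tumor_ids()
    for i, tumor in enumerate(tumor_ids):
        subtype = subtypes[i % config.n_subtypes]
        labels[tumor] = subtype
        cols[tumor] = cent[:, i % config.n_subtypes] + rng.normal(
            0.0, config.noise_sd, size=config.n_genes
        )
    matrix = pd.DataFrame(cols, index=genes)
    return matrix, centroids, pd.Series(labels, name="subtype")


def generate_signature_matrix(
    n_signatures: int = 5, seed: int = 0, concentration: float = 0.15
) -> pd.DataFrame:
    """Synthetic reference signature matrix (96 x n_signatures).

    Columns are independent Dirichlet draws with a small concentration, so
    each synthetic signature is sparse and peaked like real mutational
    signatures; columns sum to 1.  This is a synthetic stand-in — load a
    COSMIC-layout TSV for real reference signatures.
    """
    if n_signatures < 1:
        raise InvalidConfigError("n_signatures must be >= 1")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    return pd.DataFrame(
        probs,
        index=list(contexts.CONTEXT_CLASSES),
        columns=[f"synthetic_signature_{i + 1}" for i in range(n_signatures)],
    )


def _resolve_weights(
    config: SyntheticCohortConfig, reference: pd.DataFrame
) -> np.ndarray:
    """Per-tumor mixture weights, shape (n_tumors, n_signatures)."""
    n_sig = reference.shape[1]
    if config.signature_weights is None:
        w = np.full((config.n_tumors, n_sig), 1.0 / n_sig)
        return w
    arr = np.asarray(config.signature_weights, dtype=float)
    if arr.ndim == 1:
        arr = np.tile(arr, (config.n_tumors, 1))
    if arr.shape != (config.n_tumors, n_sig):
        raise InvalidConfigError(
            f"signature_weights shape {arr.shape} incompatible with "
            f"{config.n_tumors} tumors x {n_sig} signatures"
        )
    if (arr < 0).any() or not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidConfigError("signature_weights must be >= 0 and sum to 1 per tumor")
    return arr


def _context_on_random_strand(label: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """Reference-strand (ref, alt, trinucleotide) for a 96-class label,
    presented on the pyrimidine or purine strand with equal probability."""
    five, ref, alt, three = contexts.parse_class(label)
    tri = five + ref + three
    if rng.random() < 0.5:
        return contexts.revcomp(ref), contexts.revcomp(alt), contexts.revcomp(tri)
    return ref, alt, tri


def generate_variant_table(
    config: SyntheticCohortConfig,
    reference_signatures: pd.DataFrame,
    census_genes: Sequence[str] = (),
) -> tuple[pd.DataFrame, set[tuple[str, int]]]:
    """Candidate somatic-variant table drawn from known signature mixtures.

    Passing records draw their 96-context class from the tumor's mixture of
    the reference signatures and are constructed to satisfy every hard
    filter; a fraction ``filter_fail_fraction`` of records is planted to
    fail exactly one rule (caller flag, alt depth < 10, VAF < 0.05,
    single-strand support, or known-SNP membership), recorded in the
    ``planted_fail_rule`` column ('' for passing records).  Depths are
    Poisson around the configured mean sequencing depth.

    Returns (variant table, SNP site set for the filter).
    """
    from .mutations import validate_signature_matrix

    validate_signature_matrix(reference_signatures)
    rng = config.streams()["variants"]
    weights = _resolve_weights(config, reference_signatures)
    P = reference_signatures.to_numpy(dtype=float)
    class_labels = list(reference_signatures.index)
    gene_pool = list(census_genes) + [f"mgene_{i + 1:03d}" for i in range(50)]
    impacts = np.array(["HIGH", "MODERATE", "LOW", "MODIFIER"])
    impact_p = np.array([0.05, 0.25, 0.30, 0.40])
    rows = []
    snp_sites: set[tuple[str, int]] = set()
    fail_rules = ("caller_pass", "depth", "vaf", "strand", "snp")
    pos_counter = 1000
    for t_idx, tumor in enumerate(config.tumor_ids()):
        mix = P @ weights[t_idx]
        n = config.n_mutations_per_tumor
        n_fail = int(round(config.filter_fail_fraction * n))
        planted = [""] * (n - n_fail) + [fail_rules[i % len(fail_rules)] for i in range(n_fail)]
        class_idx = rng.choice(len(class_labels), size=n, p=mix)
        for k in range(n):
            rule = planted[k]
            ref, alt, tri = _context_on_random_strand(class_labels[class_idx[k]], rng)
            pos_counter += int(rng.integers(10, 5000))
            chrom = f"chr{int(rng.integers(1, 20))}"
            total = int(max(20, rng.poisson(config.mean_depth)))
            vaf = float(rng.uniform(0.1, 0.6))
            alt_depth = int(np.clip(rng.binomial(total, vaf), 10, total))
            caller_pass = True
            if rule == "depth":
                # alt depth 2..9 with a healthy VAF so only the depth rule fails
                alt_depth = int(rng.integers(2, 10))
                total = int(round(alt_depth / rng.uniform(0.1, 0.4)))
            elif rule == "vaf":
                alt_depth = 10
                total = 250  # VAF 0.04
            elif rule == "caller_pass":
                caller_pass = False
            fwd = int(rng.integers(1, alt_depth)) if alt_depth >= 2 else alt_depth
            rev = alt_depth - fwd
            if rule == "strand":
                fwd, rev = alt_depth, 0
            if rule == "snp":
                snp_sites.add((chrom, pos_counter))
            gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
            impact = str(rng.choice(impacts, p=impact_p))
            aa_change = ""
            if impact in ("HIGH", "MODERATE") and rng.random() < 0.5:
                a, b = rng.choice(len(_AA3), size=2, replace=False)
                aa_change = f"{_AA3[a]}{int(rng.integers(1, 900))}{_AA3[b]}"
            rows.append((tumor, chrom, pos_counter, ref, alt, total, alt_depth,
                         fwd, rev, caller_pass, gene, impact, aa_change, tri, rule))
    records = pd.DataFrame(
        rows,
        columns=[
            "tumor_id", "chrom", "pos", "ref_allele", "alt_allele", "total_depth",
            "alt_depth", "alt_forward", "alt_reverse", "caller_pass", "gene",
            "impact", "aa_change", "trinucleotide", "planted_fail_rule",
        ],
    )
    return records, snp_sites


def generate_census(n_genes: int = 20, seed: int = 0) -> pd.DataFrame:
    """Synthetic cancer-gene-census-like table: gene, role, alteration."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_genes):
        role = "oncogene" if rng.random() < 0.5 else "TSG"
        alteration = "amplification" if role == "oncogene" else "deletion"
        if rng.random() < 0.2:
            role, alteration = "oncogene,TSG", "amplification,deletion"
        rows.append((f"census_{i + 1:02d}", role, alteration))
    return pd.DataFrame(rows, columns=["gene", "role", "alteration"])


def generate_cna_profiles(
    config: SyntheticCohortConfig, census: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Gene-level CNA profiles with planted drivers and a near-identical pair.

    Statuses are drawn from {-2,-1,0,1,2}: non-neutral with probability
    ``cna_event_rate``, amplification-biased (65% of events are gains, the
    cohort's amplified fraction).  One planted pair of tumors shares >= 95%
    of gene statuses (the last tumor copies the first with 2% of genes
    redrawn), and planted driver events set census amplification genes to
    +2 / deletion genes to -2 in alternating tumors.

    Returns (genes x tumors status matrix, ground truth dict with keys
    ``planted_pair`` and ``planted_drivers`` [(tumor, gene, status), ...]).
    """
    rng = config.streams()["cna"]
    census_genes = list(census["gene"])
    n_extra = max(0, config.n_cna_genes - len(census_genes))
    genes = census_genes + [f"cgene_{i + 1:04d}" for i in range(n_extra)]
    tumors = config.tumor_ids()
    event = rng.random((len(genes), len(tumors))) < config.cna_event_rate
    level = rng.choice(
        [-2, -1, 1, 2], size=event.shape, p=[0.10, 0.25, 0.45, 0.20]
    )
    statuses = np.where(event, level, 0)

    # planted events are part of the aberration process: at rate 0 the
    # profiles are entirely neutral and the planted pair is trivially identical
    alt_map = census.set_index("gene")["alteration"].astype(str)
    planted_drivers = []
    if config.cna_event_rate > 0:
        for j, gene in enumerate(census_genes):
            tumor_idx = j % len(tumors)
            kinds = {k.strip() for k in alt_map[gene].split(",")}
            if rng.random() < 0.5:
                status = 2 if "amplification" in kinds else -2
                statuses[j, tumor_idx] = status
                planted_drivers.append((tumors[tumor_idx], gene, status))

    pair = None
    if len(tumors) >= 2 and len(genes) >= 20:
        a, b = 0, len(tumors) - 1
        statuses[:, b] = statuses[:, a]
        if config.cna_event_rate > 0:
            n_flip = max(1, int(round(0.02 * len(genes))))
            flip = rng.choice(len(genes), size=n_flip, replace=False)
            for g in flip:
                choices = [s for s in (-2, -1, 0, 1, 2) if s != statuses[g, a]]
                statuses[g, b] = choices[int(rng.integers(0, len(choices)))]
        pair = (tumors[a], tumors[b])
        planted_drivers = [(t, g, s) for (t, g, s) in planted_drivers if t != tumors[b]]

    profiles = pd.DataFrame(statuses, index=genes, columns=tumors)
    return profiles, {"planted_pair": pair, "planted_drivers": planted_drivers}


def generate_trinuc_freqs(seed: int = 0, tg_boost: float = 0.0) -> pd.Series:
    """Synthetic genome trinucleotide frequency table over the 32
    pyrimidine-centered contexts (sums to 1).

    ``tg_boost`` adds extra mass to NTG contexts before renormalization,
    for constructing backgrounds with a known 3'-G proportion.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(32, 5.0))
    s = pd.Series(freqs, index=list(contexts.PYRIMIDINE_CONTEXTS_32))
    if tg_boost:
        mask = [c[1] == "T" and c[2] == "G" for c in s.index]
        s[mask] = s[mask] + tg_boost / sum(mask)
        s = s / s.sum()
    return s
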