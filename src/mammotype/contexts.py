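"""96-class trinucleotide substitution contexts (pyrimidine-strand convention).

Single-nucleotide substitutions are classified by the mutated pyrimidine
(C or T), the alternate base, and the two flanking reference bases, giving
6 substitution types x 4 five-prime bases x 4 three-prime bases = 96
classes, written e.g. ``A[T>A]G``.  Mutations reported with a purine
reference base are reverse-complemented onto the pyrimidine strand.
"""

from __future__ import annotations

from itertools import product

__all__ = [
    "SUBSTITUTION_TYPES",
    "CONTEXT_CLASSES",
    "CLASS_INDEX",
    "PYRIMIDINE_CONTEXTS_32",
    "revcomp",
    "classify_snv",
    "parse_class",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the six pyrimidine-strand substitution types, COSMIC ordering
SUBSTITUTION_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 canonical classes, grouped by substitution type, flanks alphabetical
CONTEXT_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five, three in product("ACGT", repeat=2)
)

CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONTEXT_CLASSES)}

#: the 32 pyrimidine-centered trinucleotides (genome-background support)
PYRIMIDINE_CONTEXTS_32: tuple[str, ...] = tuple(
    f"{five}{mid}{three}" for mid in "CT" for five, three in product("ACGT", repeat=2)
)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def classify_snv(ref: str, alt: str, trinucleotide: str) -> str:
    """Map an SNV to its 96-class label, collapsing to the pyrimidine strand.

    ``trinucleotide`` is the reference-strand 3-mer centered on the mutated
    base; its middle base must equal ``ref``.  A purine reference (A/G) is
    reverse-complemented, e.g. A>T in context CAT becomes T>A in context ATG.
    """
    ref, alt, trinucleotide = ref.upper(), alt.upper(), trinucleotide.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt or len(trinucleotide) != 3:
        raise ValueError(f"not an SNV: {ref}>{alt} in {trinucleotide!r}")
    if trinucleotide[1] != ref:
        raise ValueError(
            f"trinucleotide {trinucleotide!r} middle base does not match ref {ref!r}"
        )
    if ref in "AG":
        ref, alt, trinucleotide = revcomp(ref), revcomp(alt), revcomp(trinucleotide)
    label = f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"
    if label not in CLASS_INDEX:
        raise ValueError(f"invalid context class {label!r}")
    return label


def parse_class(label: str) -> tuple[str, str, str, str]:
    """Split a class label into (5' base, ref, alt, 3' base)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    if label not in CLASS_INDEX:
        raise ValueError(f"invalid context class {label!r}")
    return five, ref, alt, three
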