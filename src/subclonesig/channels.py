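"""Mutation channel schemes and classifiers.

Each somatic mutation class (single-base substitution, doublet-base
substitution, small insertion/deletion, structural rearrangement) is
summarised over its own fixed, ordered set of *channels*; a sample's
channel counts form its mutational catalog and, normalized, its profile.

Schemes provided here:

* SBS-96 — six pyrimidine-referenced substitution classes (C>A, C>G, C>T,
  T>A, T>C, T>G) in their immediate 5'/3' trinucleotide context
  (6 x 4 x 4 = 96 channels). Purine-referenced input is reverse
  complemented, which swaps the flanks.
* SBS-6 — the substitution classes alone, with a collapse map from SBS-96.
* DBS-78 — strand-agnostic doublet substitutions. 16 x 9 ordered doublet
  changes collapse to 78 under reverse complementation.
* DBS-1248 — doublets extended with one base of 5' and 3' context
  (4 x 78 x 4), with a collapse map onto DBS-78.
* Indel — class (ins/del) x motif content/size (1bp C/G, 1bp T/A, longer)
  x junction (repeat-mediated, microhomology, none).
* Rearrangement — tandem duplication / deletion / inversion in five size
  bins, plus translocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

from .errors import (
    CollapseMapError,
    IndelTooLargeError,
    InvalidInputError,
    NotADoubletError,
)

BASES = "ACGT"
PYRIMIDINES = "CT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: size bins for intra-chromosomal rearrangements, upper bounds in bp
REARRANGEMENT_BINS = (
    ("<10kb", 10_000),
    ("10-100kb", 100_000),
    ("100kb-1Mb", 1_000_000),
    ("1-10Mb", 10_000_000),
    (">10Mb", None),
)

INDEL_MAX_BP = 100


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_bases(seq: str, what: str) -> None:
    if not seq or any(b not in BASES for b in seq):
        raise InvalidInputError(f"{what} must be a non-empty ACGT string, got {seq!r}")


@dataclass(frozen=True)
class ChannelScheme:
    """An ordered, named set of channel labels for one mutation class.

    Parameters
    ----------
    name : str
        Scheme identifier (e.g. ``"SBS96"``).
    labels : tuple of str
        Unique channel labels in canonical order; catalogs built on this
        scheme keep rows in exactly this order.
    class_covered : str
        Mutation class the scheme classifies: one of ``SBS``, ``DBS``,
        ``INDEL``, ``REARR``.
    collapse_map : mapping, optional
        Total map from a finer scheme's labels onto this scheme's labels;
        used by :func:`collapse_signature`.
    """

    name: str
    labels: tuple
    class_covered: str
    collapse_map: Optional[Mapping[str, str]] = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise InvalidInputError(f"duplicate labels in scheme {self.name}")
        if self.collapse_map is not None:
            targets = set(self.collapse_map.values())
            if not targets <= set(self.labels):
                raise InvalidInputError(
                    f"collapse_map of {self.name} maps outside its label set"
                )
            if targets != set(self.labels):
                raise InvalidInputError(
                    f"collapse_map of {self.name} is not surjective onto its labels"
                )
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise InvalidInputError(f"{label!r} is not a channel of {self.name}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index


# ---------------------------------------------------------------------------
# SBS
# ---------------------------------------------------------------------------

def classify_sbs(context: str, ref: str, alt: str) -> str:
    """Channel label for a single-base substitution in trinucleotide context.

    ``context`` is the reference trinucleotide centred on the mutated base.
    Purine-referenced calls are reverse complemented (flanks swap), so the
    label is strand-agnostic: ``classify_sbs(revcomp(ctx), comp(ref),
    comp(alt))`` equals ``classify_sbs(ctx, ref, alt)``.
    """
    if len(context) != 3:
        raise InvalidInputError(f"context must have length 3, got {context!r}")
    _check_bases(context, "context")
    _check_bases(ref, "ref")
    _check_bases(alt, "alt")
    if len(ref) != 1 or len(alt) != 1:
        raise InvalidInputError("ref and alt must be single bases")
    if context[1] != ref:
        raise InvalidInputError(
            f"middle of context {context!r} does not match ref {ref!r}"
        )
    if ref == alt:
        raise InvalidInputError("ref and alt are identical")
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def sbs96_scheme() -> ChannelScheme:
    labels = tuple(
        f"{f5}[{sub}]{f3}"
        for sub in SUBSTITUTION_CLASSES
        for f5 in BASES
        for f3 in BASES
    )
    return ChannelScheme("SBS96", labels, "SBS")


def sbs6_scheme() -> ChannelScheme:
    """Six substitution classes, with the SBS-96 collapse map attached."""
    cmap = {
        f"{f5}[{sub}]{f3}": sub
        for sub in SUBSTITUTION_CLASSES
        for f5 in BASES
        for f3 in BASES
    }
    return ChannelScheme("SBS6", SUBSTITUTION_CLASSES, "SBS", collapse_map=cmap)


# ---------------------------------------------------------------------------
# DBS
# ---------------------------------------------------------------------------

def _canonical_doublet(ref: str, alt: str) -> tuple:
    """Canonical orientation of a doublet change.

    Of the two strand readings ``(ref, alt)`` and ``(rc(ref), rc(alt))``
    the one with the lexicographically smaller ref wins; equal refs fall
    back to the smaller alt. Returns ``(ref, alt, flipped)``.
    """
    rr, ra = revcomp(ref), revcomp(alt)
    if (rr, ra) < (ref, alt):
        return rr, ra, True
    return ref, alt, False


def classify_dbs(ref: str, alt: str) -> str:
    """Strand-agnostic channel label ``"RR>AA"`` for a doublet substitution."""
    _check_bases(ref, "ref dinucleotide")
    _check_bases(alt, "alt dinucleotide")
    if len(ref) != 2 or len(alt) != 2:
        raise InvalidInputError("doublets must be 2-nucleotide strings")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise NotADoubletError(
            f"{ref}>{alt}: both positions must change in a doublet substitution"
        )
    cref, calt, _ = _canonical_doublet(ref, alt)
    return f"{cref}>{calt}"


def _doublet_changes():
    for ref in (a + b for a in BASES for b in BASES):
        for alt in (a + b for a in BASES for b in BASES):
            if ref[0] != alt[0] and ref[1] != alt[1]:
                yield ref, alt


@lru_cache(maxsize=1)
def _dbs78_labels() -> tuple:
    return tuple(sorted({classify_dbs(r, a) for r, a in _doublet_changes()}))


def dbs78_scheme() -> ChannelScheme:
    return ChannelScheme("DBS78", _dbs78_labels(), "DBS")


def classify_dbs_flanked(f5: str, ref: str, alt: str, f3: str) -> str:
    """Doublet channel extended with one base of 5' and 3' context.

    The doublet core is strand-canonicalized exactly as in
    :func:`classify_dbs`; when the core flips, the flanks are reverse
    complemented and swapped with it. Doublet pairs that read identically
    on both strands keep the input flank orientation, so the label space
    is the full 4 x 78 x 4 = 1248 product.
    """
    for b, what in ((f5, "5' flank"), (f3, "3' flank")):
        _check_bases(b, what)
        if len(b) != 1:
            raise InvalidInputError(f"{what} must be a single base")
    classify_dbs(ref, alt)  # validates the core
    cref, calt, flipped = _canonical_doublet(ref, alt)
    if flipped:
        f5, f3 = revcomp(f3), revcomp(f5)
    return f"{f5}[{cref}>{calt}]{f3}"


@lru_cache(maxsize=1)
def _dbs1248_labels() -> tuple:
    return tuple(
        f"{f5}[{core}]{f3}"
        for core in _dbs78_labels()
        for f5 in BASES
        for f3 in BASES
    )


def dbs1248_scheme() -> ChannelScheme:
    return ChannelScheme("DBS1248", _dbs1248_labels(), "DBS")


def dbs78_from_1248_scheme() -> ChannelScheme:
    """DBS-78 carrying the collapse map from flank-extended DBS-1248 labels."""
    cmap = {lab: lab.split("[")[1].split("]")[0] for lab in _dbs1248_labels()}
    return ChannelScheme("DBS78", _dbs78_labels(), "DBS", collapse_map=cmap)


# ---------------------------------------------------------------------------
# Indels
# ---------------------------------------------------------------------------

_INDEL_JUNCTIONS = ("none", "rep_2", "rep_3", "rep_4", "rep_5+")
_INDEL_SIZES = ("1bp_C/G", "1bp_T/A", "longer")


@lru_cache(maxsize=1)
def _indel_labels() -> tuple:
    labels = []
    for cls in ("del", "ins"):
        for size in _INDEL_SIZES:
            for j in _INDEL_JUNCTIONS:
                labels.append(f"{cls}.{size}.{j}")
            if cls == "del" and size == "longer":
                labels.append("del.longer.mh")
    return tuple(labels)


def indel_scheme() -> ChannelScheme:
    return ChannelScheme("ID31", _indel_labels(), "INDEL")


def _tandem_copies(motif: str, flank5: str, flank3: str) -> int:
    """Perfect adjacent copies of ``motif`` in the flanks, plus the event copy."""
    m = len(motif)
    n = 1
    i = 0
    while flank3[i : i + m] == motif:
        n += 1
        i += m
    i = len(flank5)
    while i >= m and flank5[i - m : i] == motif:
        n += 1
        i -= m
    return n


def _microhomology(motif: str, flank5: str, flank3: str) -> int:
    """Longest junctional identity (bp) between the deleted motif and a flank."""
    best = 0
    for k in range(len(motif) - 1, 0, -1):
        if flank3[:k] == motif[:k]:
            best = k
            break
    for k in range(len(motif) - 1, best, -1):
        if flank5[-k:] == motif[-k:]:
            best = k
            break
    return best


def classify_indel(mclass: str, seq: str, flank5: str, flank3: str) -> str:
    """Channel label for a small insertion or deletion.

    Parameters
    ----------
    mclass : {"INS", "DEL"}
    seq : str
        The inserted or deleted sequence itself (no anchor base).
    flank5, flank3 : str
        Reference sequence immediately 5' and 3' of the event; at least
        50 bp each so repeat runs and microhomology resolve.

    The junction attribute is ``rep_N`` when the motif sits in a perfect
    tandem run of N copies (counting the event copy; N capped at 5+),
    ``mh`` for deletions of >= 2 bp with junctional microhomology outside
    a repeat run, and ``none`` otherwise.
    """
    if mclass not in ("INS", "DEL"):
        raise InvalidInputError(f"mclass must be INS or DEL, got {mclass!r}")
    _check_bases(seq, "indel sequence")
    if len(seq) >= INDEL_MAX_BP:
        raise IndelTooLargeError(
            f"indel of {len(seq)} bp is at/above the {INDEL_MAX_BP} bp small-indel limit"
        )
    if len(flank5) < 50 or len(flank3) < 50:
        raise InvalidInputError("flanks must be at least 50 bp each")
    _check_bases(flank5, "5' flank")
    _check_bases(flank3, "3' flank")

    cls = "ins" if mclass == "INS" else "del"
    if len(seq) == 1:
        size = "1bp_C/G" if seq in "CG" else "1bp_T/A"
    else:
        size = "longer"

    copies = _tandem_copies(seq, flank5, flank3)
    if copies >= 2:
        junction = "rep_5+" if copies >= 5 else f"rep_{copies}"
    elif cls == "del" and len(seq) >= 2 and _microhomology(seq, flank5, flank3) >= 1:
        junction = "mh"
    else:
        junction = "none"
    return f"{cls}.{size}.{junction}"


# ---------------------------------------------------------------------------
# Rearrangements
# ---------------------------------------------------------------------------

_REARR_PREFIX = {
    "tandem_duplication": "TD",
    "deletion": "DEL",
    "inversion": "INV",
}


@lru_cache(maxsize=1)
def _rearrangement_labels() -> tuple:
    labels = [
        f"{p}.{b}" for p in ("TD", "DEL", "INV") for b, _ in REARRANGEMENT_BINS
    ]
    labels.append("TRANS")
    return tuple(labels)


def rearrangement_scheme() -> ChannelScheme:
    return ChannelScheme("RS16", _rearrangement_labels(), "REARR")


def classify_rearrangement(rtype: str, size_bp: Optional[int] = None) -> str:
    """Channel label for a structural rearrangement.

    Intra-chromosomal events (tandem duplication, deletion, inversion)
    carry a positive fragment size and fall into five log-spaced size
    bins; translocations are a single sizeless channel.
    """
    if rtype == "translocation":
        if size_bp is not None:
            raise InvalidInputError("translocations do not carry a size")
        return "TRANS"
    if rtype not in _REARR_PREFIX:
        raise InvalidInputError(f"unknown rearrangement type {rtype!r}")
    if size_bp is None or size_bp <= 0:
        raise InvalidInputError(f"{rtype} requires a positive size_bp")
    for name, upper in REARRANGEMENT_BINS:
        if upper is None or size_bp < upper:
            return f"{_REARR_PREFIX[rtype]}.{name}"
    raise AssertionError("unreachable")  # pragma: no cover
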