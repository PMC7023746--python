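"""Mutation records, catalogs and signature profiles.

A :class:`Catalog` is the channels x samples matrix of non-negative
integer counts for one mutation class; a sample's *burden* is its column
sum and its *profile* is the column normalized to sum 1. A
:class:`SignatureProfile` is a non-negative, unit-sum weight vector over
a scheme's channels (the empty signature sums to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .channels import (
    ChannelScheme,
    classify_dbs,
    classify_indel,
    classify_rearrangement,
    classify_sbs,
)
from .errors import (
    CollapseMapError,
    InvalidInputError,
    ReferenceLookupError,
    SchemeMismatchError,
    ZeroBurdenError,
)

MUTATION_CLASSES = ("SBS", "DBS", "INS", "DEL", "REARR")


@dataclass
class MutationRecord:
    """One somatic call, ready for channel classification.

    ``pos`` is 1-based as in VCF. For substitutions ``ref``/``alt`` are the
    substituted bases; for indels they hold the deleted / inserted sequence
    itself (the other field empty, no anchor base). Rearrangements carry
    ``rtype`` and ``size_bp`` instead of alleles.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mclass: str
    vaf: Optional[float] = None
    depth: Optional[int] = None
    rtype: Optional[str] = None
    size_bp: Optional[int] = None

    def __post_init__(self):
        if self.mclass not in MUTATION_CLASSES:
            raise InvalidInputError(f"unknown mutation class {self.mclass!r}")
        if self.pos < 1:
            raise InvalidInputError(f"pos must be >= 1, got {self.pos}")
        if self.mclass != "REARR" and self.ref == self.alt:
            raise InvalidInputError("ref and alt must differ")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise InvalidInputError(f"vaf must lie in [0, 1], got {self.vaf}")

    @property
    def key(self) -> tuple:
        """Genotype-agnostic variant identity used for sharing analyses."""
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# reference access (single audited 1-based -> 0-based conversion point)
# ---------------------------------------------------------------------------

def fetch_reference(reference, chrom: str, start1: int, end1: int) -> str:
    """Reference slice for the 1-based closed interval [start1, end1].

    ``reference`` may be a pyfaidx ``Fasta``, a pysam ``FastaFile``, a
    plain ``{chrom: sequence}`` mapping, or any object exposing
    ``fetch(chrom, start0, end0)`` over 0-based half-open coordinates.
    Out-of-range flanks are silently truncated at contig edges.
    """
    start0, end0 = start1 - 1, end1  # the only 1-based -> 0-based conversion
    start0 = max(start0, 0)
    try:
        if hasattr(reference, "fetch"):
            seq = reference.fetch(chrom, start0, end0)
        elif isinstance(reference, dict) or not hasattr(reference, "get_seq"):
            seq = reference[chrom][start0:end0]
        else:  # pyfaidx Fasta
            seq = str(reference[chrom][start0:end0])
    except (KeyError, ValueError, IndexError) as exc:
        raise ReferenceLookupError(
            f"cannot fetch {chrom}:{start1}-{end1} from reference"
        ) from exc
    return str(seq).upper()


def _classify_record(rec: MutationRecord, scheme: ChannelScheme, reference) -> str:
    """Channel label for one record under ``scheme``; may raise InvalidInputError."""
    cc = scheme.class_covered
    if cc == "SBS":
        ctx = fetch_reference(reference, rec.chrom, rec.pos - 1, rec.pos + 1)
        if len(ctx) != 3:
            raise ReferenceLookupError(
                f"{rec.sample_id} {rec.chrom}:{rec.pos}: context truncated at contig edge"
            )
        label = classify_sbs(ctx, rec.ref, rec.alt)
        if scheme.name == "SBS6":
            label = scheme.collapse_map[label] if scheme.collapse_map else label
        return label
    if cc == "DBS":
        return classify_dbs(rec.ref, rec.alt)
    if cc == "INDEL":
        if rec.mclass == "DEL":
            seq = rec.ref
            f5 = fetch_reference(reference, rec.chrom, rec.pos - 60, rec.pos - 1)
            f3 = fetch_reference(
                reference, rec.chrom, rec.pos + len(seq), rec.pos + len(seq) + 59
            )
        else:
            seq = rec.alt
            f5 = fetch_reference(reference, rec.chrom, rec.pos - 60, rec.pos - 1)
            f3 = fetch_reference(reference, rec.chrom, rec.pos, rec.pos + 59)
        return classify_indel(rec.mclass, seq, f5, f3)
    if cc == "REARR":
        return classify_rearrangement(rec.rtype, rec.size_bp)
    raise SchemeMismatchError(f"scheme covers unknown class {cc!r}")


_CLASS_FOR_SCHEME = {"SBS": ("SBS",), "DBS": ("DBS",), "INDEL": ("INS", "DEL"),
                     "REARR": ("REARR",)}


@dataclass
class Catalog:
    """Channels x samples matrix of classified mutation counts."""

    scheme: ChannelScheme
    samples: List[str]
    counts: np.ndarray
    unclassified: List[tuple] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.scheme), len(self.samples)):
            raise InvalidInputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.scheme)} channels x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise InvalidInputError("catalog counts must be non-negative")

    # -- accessors -----------------------------------------------------
    def burdens(self) -> pd.Series:
        """Per-sample total mutation count (column sums)."""
        return pd.Series(self.counts.sum(axis=0), index=self.samples)

    def column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.samples.index(sample_id)
        except ValueError:
            raise InvalidInputError(f"sample {sample_id!r} not in catalog") from None
        return self.counts[:, j]

    def profile(self, sample_id: str) -> "SignatureProfile":
        col = self.column(sample_id)
        total = col.sum()
        if total == 0:
            raise ZeroBurdenError(f"sample {sample_id!r} has zero burden")
        return SignatureProfile(self.scheme, col / total)

    def subset(self, sample_ids: Sequence[str]) -> "Catalog":
        cols = [self.samples.index(s) for s in sample_ids]
        return Catalog(self.scheme, list(sample_ids), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.scheme.labels), columns=self.samples
        )


def build_catalog(
    records: Iterable[MutationRecord],
    scheme: ChannelScheme,
    reference=None,
    samples: Optional[Sequence[str]] = None,
) -> Catalog:
    """Classify ``records`` under ``scheme`` and tabulate counts per sample.

    Records whose context contains a non-ACGT base (e.g. N) are collected
    in ``catalog.unclassified`` as ``(record, reason)`` pairs rather than
    aborting the run; a missing reference locus still raises, naming the
    record. ``samples`` fixes column order (and admits all-zero columns);
    by default columns follow first appearance.
    """
    wanted = _CLASS_FOR_SCHEME[scheme.class_covered]
    records = list(records)
    for rec in records:
        if rec.mclass not in wanted:
            raise InvalidInputError(
                f"record {rec.key} has class {rec.mclass}, scheme covers {wanted}"
            )
    if samples is None:
        seen = dict.fromkeys(r.sample_id for r in records)
        samples = list(seen)
    samples = list(samples)
    col = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(scheme), len(samples)), dtype=np.int64)
    unclassified: List[tuple] = []
    for rec in records:
        if rec.sample_id not in col:
            raise InvalidInputError(f"record sample {rec.sample_id!r} not in sample list")
        try:
            label = _classify_record(rec, scheme, reference)
        except InvalidInputError as exc:
            unclassified.append((rec, str(exc)))
            continue
        counts[scheme.index(label), col[rec.sample_id]] += 1
    return Catalog(scheme, samples, counts, unclassified)


@dataclass
class SignatureProfile:
    """Non-negative weights over a scheme's channels, summing to 1 (or 0)."""

    scheme: ChannelScheme
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.scheme),):
            raise InvalidInputError(
                f"weights length {self.weights.size} != {len(self.scheme)} channels"
            )
        if (self.weights < 0).any():
            raise InvalidInputError("signature weights must be non-negative")
        total = self.weights.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise InvalidInputError(
                f"signature weights must sum to 1 (or 0 for empty), got {total}"
            )

    @classmethod
    def from_counts(cls, scheme: ChannelScheme, counts) -> "SignatureProfile":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        return cls(scheme, counts / total if total > 0 else np.zeros_like(counts))

    @property
    def is_empty(self) -> bool:
        return self.weights.sum() == 0

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.scheme.labels))


def collapse_signature(
    sig: SignatureProfile, target: ChannelScheme
) -> SignatureProfile:
    """Collapse a fine-scheme signature onto ``target`` via its collapse map.

    Each target weight is the sum of the fine weights mapped onto it, so
    total weight is conserved exactly.
    """
    if target.collapse_map is None:
        raise CollapseMapError(f"target scheme {target.name} has no collapse map")
    out = np.zeros(len(target))
    for label, w in zip(sig.scheme.labels, sig.weights):
        try:
            tgt = target.collapse_map[label]
        except KeyError:
            raise CollapseMapError(
                f"fine label {label!r} missing from collapse map of {target.name}"
            ) from None
        out[target.index(tgt)] += w
    return SignatureProfile(target, out)
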