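"""Synthetic subclone experiments.

Generates complete, fully-labelled experiments with the statistical
structure the analysis framework assumes, so every module is testable
without external data:

* a random reference sequence with an index from trinucleotide context
  to genomic positions, so sampled substitutions can be *placed* at loci
  whose context matches their channel (classification round-trips
  exactly);
* genealogical sharing — parental clones carry background mutations that
  every descendant subclone inherits, plus private mutations accrued
  after the single-cell bottleneck;
* signature mixtures — experimental subclones add a multinomial draw
  from a treatment signature on top of the background signature;
* read-level VAFs — binomial read sampling at the stated depth around
  the ploidy-expected allele fraction;
* planted QC failures — a mislabelled (wrong) parent, a mixed parental
  population, or a polyclonal subclone.

All generation is reproducible from the config seed; the returned truth
record is sufficient to score every downstream check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .catalog import MutationRecord, SignatureProfile
from .channels import BASES, ChannelScheme, revcomp, sbs96_scheme
from .errors import ConfigError, InvalidInputError, PlacementError
from .qc import LineageManifest, expected_vaf

SCENARIOS = ("clean", "wrong_parent", "mixed_parental", "polyclonal")

#: sibling grouping planted by the mixed_parental scenario: 0-based indices
#: of the subclones drawn from the second, hidden parent ({2,3,5} of six,
#: leaving {1,4,6} on the declared lineage)
MIXED_SECOND_LINEAGE = (1, 2, 4)

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


class ReferenceGenome:
    """A single-contig random reference with context-indexed positions."""

    def __init__(self, name: str, sequence: str):
        self.name = name
        self.sequence = sequence
        self._context_index: Optional[Dict[str, np.ndarray]] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        if chrom != self.name:
            raise KeyError(chrom)
        return self.sequence[max(start0, 0) : end0]

    def __getitem__(self, chrom: str) -> str:
        if chrom != self.name:
            raise KeyError(chrom)
        return self.sequence

    # -- context index -------------------------------------------------
    def context_positions(self) -> Dict[str, np.ndarray]:
        """Map pyrimidine-strand trinucleotide -> 1-based middle positions.

        A site whose middle base is a purine is indexed under the reverse
        complement of its triplet, mirroring channel canonicalization.
        """
        if self._context_index is None:
            codes = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
            lut = np.full(256, -1, dtype=np.int8)
            for b, i in _BASE_CODE.items():
                lut[ord(b)] = i
            s = lut[codes].astype(np.int64)
            a, b, c = s[:-2], s[1:-1], s[2:]
            fwd = a * 16 + b * 4 + c
            rev = (3 - c) * 16 + (3 - b) * 4 + (3 - a)
            canon = np.where((b == 1) | (b == 3), fwd, rev)  # C=1, T=3
            mid_pos = np.arange(2, len(s))  # 1-based position of middle base
            index: Dict[str, np.ndarray] = {}
            for f5 in BASES:
                for mid in "CT":
                    for f3 in BASES:
                        code = (
                            _BASE_CODE[f5] * 16
                            + _BASE_CODE[mid] * 4
                            + _BASE_CODE[f3]
                        )
                        index[f5 + mid + f3] = mid_pos[canon == code]
            self._context_index = index
        return self._context_index

    def write_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), line_width):
                fh.write(self.sequence[i : i + line_width] + "\n")


def make_reference(length: int, seed: int, name: str = "chrSim") -> ReferenceGenome:
    """Uniform-ACGT random reference, deterministic in ``seed``."""
    if length < 10_000:
        raise InvalidInputError(
            f"reference length must be >= 10000 bp, got {length}"
        )
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    return ReferenceGenome(name, seq)


# ---------------------------------------------------------------------------
# signature construction helpers
# ---------------------------------------------------------------------------

def flat_signature(scheme: Optional[ChannelScheme] = None) -> SignatureProfile:
    scheme = scheme or sbs96_scheme()
    return SignatureProfile(scheme, np.full(len(scheme), 1.0 / len(scheme)))


def peaked_signature(
    n_peaks: int = 5,
    seed: int = 0,
    scheme: Optional[ChannelScheme] = None,
    peak_weight: float = 0.9,
) -> SignatureProfile:
    """A sparse signature with ``n_peaks`` dominant channels.

    ``peak_weight`` of the mass is spread evenly over the peaks, the rest
    over all remaining channels — the shape treatments such as strong
    genotoxins leave (few prominent peaks over a faint floor).
    """
    scheme = scheme or sbs96_scheme()
    rng = np.random.default_rng(seed)
    peaks = rng.choice(len(scheme), size=n_peaks, replace=False)
    w = np.full(len(scheme), (1.0 - peak_weight) / (len(scheme) - n_peaks))
    w[peaks] = peak_weight / n_peaks
    return SignatureProfile(scheme, w)


# ---------------------------------------------------------------------------
# mutation sampling
# ---------------------------------------------------------------------------

def _label_parts(label: str) -> Tuple[str, str, str]:
    """(context_key, ref, alt) on the pyrimidine strand for an SBS-96 label."""
    f5, rest = label[0], label[2:-2]
    f3 = label[-1]
    ref, alt = rest.split(">")
    return f5 + ref + f3, ref, alt


def sample_mutations(
    signature: SignatureProfile,
    burden: int,
    reference: ReferenceGenome,
    seed: int,
    sample_id: str = "S",
    rng: Optional[np.random.Generator] = None,
    exclude: Optional[Set[int]] = None,
) -> List[MutationRecord]:
    """Draw ``burden`` substitutions from ``signature`` and place them.

    Channel counts are one multinomial draw; each mutation lands at a
    uniformly chosen reference position whose trinucleotide context
    matches its channel (purine-strand sites get the complementary
    alleles), at distinct loci. Re-classifying the output reproduces the
    drawn channel counts exactly.
    """
    if burden < 0:
        raise InvalidInputError("burden must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if burden == 0:
        return []
    exclude = exclude if exclude is not None else set()
    index = reference.context_positions()
    counts = rng.multinomial(burden, signature.weights)
    records: List[MutationRecord] = []
    for label, k in zip(signature.scheme.labels, counts):
        if k == 0:
            continue
        key, ref, alt = _label_parts(label)
        pool = index.get(key, np.empty(0, dtype=np.int64))
        avail = pool[~np.isin(pool, list(exclude))] if exclude else pool
        if avail.size < k:
            raise PlacementError(
                f"reference has only {avail.size} free sites with context "
                f"{key} for channel {label} (need {k})"
            )
        chosen = rng.choice(avail, size=k, replace=False)
        for pos in chosen:
            pos = int(pos)
            exclude.add(pos)
            base = reference.sequence[pos - 1]
            if base in "CT":
                r, a = ref, alt
            else:
                r, a = revcomp(ref), revcomp(alt)
            records.append(
                MutationRecord(
                    sample_id=sample_id,
                    chrom=reference.name,
                    pos=pos,
                    ref=r,
                    alt=a,
                    mclass="SBS",
                )
            )
    return records


def sample_rearrangements(
    n: int, seed: int, sample_id: str = "S", chrom: str = "chrSim"
) -> List[MutationRecord]:
    """Random structural rearrangements across the four types and size bins."""
    rng = np.random.default_rng(seed)
    types = ["tandem_duplication", "deletion", "inversion", "translocation"]
    out = []
    for i in range(n):
        rtype = types[rng.integers(0, 4)]
        size = None if rtype == "translocation" else int(10 ** rng.uniform(3, 7.5))
        out.append(
            MutationRecord(
                sample_id=sample_id,
                chrom=chrom,
                pos=int(rng.integers(1, 10_000_000)),
                ref="A",
                alt="T",
                mclass="REARR",
                rtype=rtype,
                size_bp=size,
            )
        )
    return out



# ---------------------------------------------------------------------------
# full experiment simulation
# ---------------------------------------------------------------------------

@dataclass
class LineageSimConfig:
    """Generative settings for one synthetic experiment.

    Defaults emulate a six-subclone-per-parent design at 30x depth in a
    diploid model: parental clones carry 100 background mutations shared
    by descent, each subclone accrues 60 private background mutations
    across its post-bottleneck doublings, and experimental subclones add
    300 treatment-signature mutations.
    """

    n_parents: int = 2
    subclones_per_parent: int = 6
    parental_burden: int = 100
    private_burden: int = 60
    treatment_burden: int = 300
    background_signature: Optional[SignatureProfile] = None
    treatment_signature: Optional[SignatureProfile] = None
    n_experimental_parents: Optional[int] = None  # default: half (rounded down)
    ploidy: int = 2
    depth: int = 30
    seed: int = 0
    scenario: str = "clean"
    ref_length: int = 100_000
    treatment_name: str = "treated"

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        for f in ("parental_burden", "private_burden", "treatment_burden"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        if self.n_parents < 1 or self.subclones_per_parent < 1:
            raise ConfigError("need at least one parent and one subclone")
        if self.n_experimental_parents is None:
            self.n_experimental_parents = self.n_parents // 2
        if self.n_experimental_parents > self.n_parents:
            raise ConfigError("more experimental parents than parents")
        if self.scenario == "mixed_parental" and self.subclones_per_parent < 3:
            raise ConfigError("mixed_parental needs >= 3 subclones per parent")
        if self.background_signature is None:
            self.background_signature = flat_signature()
        if self.treatment_signature is None:
            self.treatment_signature = peaked_signature(seed=self.seed + 104729)


@dataclass
class SyntheticExperiment:
    """A generated experiment plus the ground truth that produced it."""

    config: LineageSimConfig
    reference: ReferenceGenome
    manifest: LineageManifest
    records: Dict[str, List[MutationRecord]]
    truth: dict

    def variant_sets(self) -> Dict[str, Set[tuple]]:
        return {s: {r.key for r in recs} for s, recs in self.records.items()}


def _assign_vafs(
    records: Sequence[MutationRecord],
    ploidy: int,
    depth: int,
    rng: np.random.Generator,
    cell_fraction: float = 1.0,
) -> None:
    p = cell_fraction * float(expected_vaf(ploidy, 1))
    for rec in records:
        reads = int(rng.binomial(depth, p))
        rec.depth = depth
        rec.vaf = reads / depth


def _clone(records: Sequence[MutationRecord], sample_id: str) -> List[MutationRecord]:
    return [
        MutationRecord(
            sample_id=sample_id,
            chrom=r.chrom,
            pos=r.pos,
            ref=r.ref,
            alt=r.alt,
            mclass=r.mclass,
        )
        for r in records
    ]


def simulate_experiment(config: LineageSimConfig) -> SyntheticExperiment:
    """Generate a full lineage experiment under ``config``.

    Parents P1..Pk each found ``subclones_per_parent`` subclones
    inheriting every parental mutation; the last
    ``n_experimental_parents`` parents' subclones are experimental, the
    rest controls. The grandparent is the mutation-free genetic
    reference. QC-failure scenarios plant their defect on the first
    (control) parent's family.
    """
    rng = np.random.default_rng(config.seed)
    reference = make_reference(config.ref_length, config.seed)
    used: Set[int] = set()

    parents = [f"P{i + 1}" for i in range(config.n_parents)]
    experimental = set(parents[config.n_parents - config.n_experimental_parents :])

    records: Dict[str, List[MutationRecord]] = {"GP": []}
    # the grandparent is the genetic reference: zero somatic calls

    children: Dict[str, List[str]] = {}
    condition: Dict[str, str] = {}
    truth: dict = {
        "scenario": config.scenario,
        "treatment_signature": None,
        "burdens": {"GP": 0},
        "polyclonal_samples": [],
        "mixed_groups": {},
        "wrong_parent_ids": [],
        "parent_of": {},
    }

    def draw_background(n, sample_id):
        return sample_mutations(
            config.background_signature,
            n,
            reference,
            seed=0,
            sample_id=sample_id,
            rng=rng,
            exclude=used,
        )

    for pi, parent in enumerate(parents):
        parental = draw_background(config.parental_burden, parent)
        _assign_vafs(parental, config.ploidy, config.depth, rng)
        records[parent] = parental
        truth["burdens"][parent] = len(parental)

        # hidden second lineage for the mixed_parental scenario
        mixed_here = config.scenario == "mixed_parental" and pi == 0
        if mixed_here:
            hidden = draw_background(config.parental_burden, parent + "_hidden")

        subs = [f"{parent}_S{j + 1}" for j in range(config.subclones_per_parent)]
        children[parent] = subs
        is_exp = parent in experimental
        for j, sub in enumerate(subs):
            second = mixed_here and j in MIXED_SECOND_LINEAGE
            inherited = _clone(hidden if second else parental, sub)
            private = draw_background(config.private_burden, sub)
            treatment: List[MutationRecord] = []
            if is_exp and config.treatment_burden > 0:
                treatment = sample_mutations(
                    config.treatment_signature,
                    config.treatment_burden,
                    reference,
                    seed=0,
                    sample_id=sub,
                    rng=rng,
                    exclude=used,
                )
            polyclonal_here = (
                config.scenario == "polyclonal" and pi == 0 and j == 0
            )
            _assign_vafs(inherited, config.ploidy, config.depth, rng)
            denovo = private + treatment
            if polyclonal_here:
                half = len(denovo) // 2
                _assign_vafs(denovo[:half], config.ploidy, config.depth, rng)
                _assign_vafs(
                    denovo[half:], config.ploidy, config.depth, rng, cell_fraction=0.5
                )
                truth["polyclonal_samples"].append(sub)
            else:
                _assign_vafs(denovo, config.ploidy, config.depth, rng)
            records[sub] = inherited + denovo
            truth["burdens"][sub] = len(records[sub])
            truth["parent_of"][sub] = parent + "_hidden" if second else parent
            condition[sub] = (
                f"experimental:{config.treatment_name}" if is_exp else "control"
            )
        if mixed_here:
            truth["mixed_groups"][parent] = [
                [s for j, s in enumerate(subs) if j not in MIXED_SECOND_LINEAGE],
                [s for j, s in enumerate(subs) if j in MIXED_SECOND_LINEAGE],
            ]

    # wrong_parent: sequence an unrelated clone in place of the first parent
    if config.scenario == "wrong_parent":
        decoy = "P_wrong"
        decoy_records = draw_background(config.parental_burden, decoy)
        _assign_vafs(decoy_records, config.ploidy, config.depth, rng)
        records[decoy] = decoy_records
        truth["burdens"][decoy] = len(decoy_records)
        first = parents[0]
        children[decoy] = children.pop(first)
        del records[first]
        del truth["burdens"][first]
        parents[0] = decoy
        truth["wrong_parent_ids"].append(decoy)

    truth["treatment_signature"] = config.treatment_signature
    manifest = LineageManifest(
        grandparent_id="GP",
        parents=parents,
        children=children,
        condition=condition,
    )
    return SyntheticExperiment(config, reference, manifest, records, truth)
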