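"""Lineage and clonality quality control for subclone experiments.

Four checks guard a signature experiment before any statistics are run:

1. *Clonality* — in a single-cell-derived subclone every de novo mutation
   is present in all cells, so its VAF concentrates at
   ``mutated_copies / ploidy`` (0.5 heterozygous diploid, 1.0 haploid,
   ~0.33 triploid). A polyclonal subclone dilutes private mutations
   across cell subpopulations, pushing mean VAF down and inflating the
   apparent burden.
2. *Relatedness* — every subclone must contain (almost) all of its
   declared parent's mutations and carry at least one private mutation.
   The shared-variant matrix across all samples exposes mislabelled
   parents and mixed parental populations.
3. *Lineage scenarios* — per parent, the sharing pattern is classified as
   ``consistent``, ``wrong_parent`` (siblings cohere but none contains
   the sequenced parent) or ``mixed_parental`` (siblings split into
   two or more sharing groups).
4. *On-target edit* — a successful CRISPR knockout leaves short indels
   inside the gRNA target window.

Copy-number stability and driver screening are deliberately not assessed
here (they need CNV calls and annotation databases); reports say so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import cluster, stats

from .catalog import MutationRecord
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    MissingSampleError,
)

#: default parent-containment threshold (fraction of parental mutations a
#: subclone must carry to be called a descendant)
THETA_PARENT = 0.90
#: default sibling-sharing threshold (shared / min burden) for cohesion
THETA_SIBLING = 0.50
#: significance level of the one-sided mean-VAF test
CLONALITY_ALPHA = 1e-3
#: effect-size floor: flag only if mean VAF < this fraction of expected
CLONALITY_EFFECT_FLOOR = 0.8
#: minimum usable mutations for a conclusive clonality verdict
MIN_CLONALITY_MUTATIONS = 20


def expected_vaf(ploidy: int, mutated_copies: int = 1) -> Fraction:
    """Expected variant allele fraction of a clonal mutation.

    Exact rational ``mutated_copies / ploidy``: with every cell carrying
    the variant on ``mutated_copies`` of ``ploidy`` allele copies, that is
    the fraction of reads expected to show it.
    """
    if ploidy < 1 or mutated_copies < 1:
        raise InvalidInputError("ploidy and mutated_copies must be positive")
    if mutated_copies > ploidy:
        raise InvalidInputError(
            f"mutated_copies ({mutated_copies}) cannot exceed ploidy ({ploidy})"
        )
    return Fraction(mutated_copies, ploidy)


@dataclass
class ClonalityReport:
    sample_id: str
    expected_vaf: float
    observed_mean_vaf: float
    n_mutations: int
    verdict: str  # "clonal" | "polyclonal_suspect"
    p_value: float
    note: str = ""


def clonality_check(
    vafs: Sequence[float],
    depths: Sequence[int],
    ploidy: int,
    mutated_copies: int = 1,
    sample_id: str = "",
    alpha: float = CLONALITY_ALPHA,
    effect_floor: float = CLONALITY_EFFECT_FLOOR,
) -> ClonalityReport:
    """Test whether a subclone's VAF distribution matches clonal expectation.

    Verdict is ``polyclonal_suspect`` only when the one-sided test that
    the mean VAF lies below ``expected_vaf(ploidy, mutated_copies)``
    rejects at ``alpha`` *and* the observed mean is below
    ``effect_floor x expected`` — the effect-size floor stops very deep
    sequencing from flagging trivial deviations.
    """
    vafs = np.asarray(
        [v for v, d in zip(vafs, depths) if v is not None and d is not None],
        dtype=float,
    )
    if vafs.size < MIN_CLONALITY_MUTATIONS:
        raise InsufficientDataError(
            f"clonality QC inconclusive: {vafs.size} usable mutations "
            f"(need >= {MIN_CLONALITY_MUTATIONS})"
        )
    exp = float(expected_vaf(ploidy, mutated_copies))
    mean = float(vafs.mean())
    t = stats.ttest_1samp(vafs, popmean=exp, alternative="less")
    p = float(t.pvalue)
    if p <= alpha and mean < effect_floor * exp:
        note = (
            "mean VAF well below clonal expectation: suspected polyclonal/mosaic "
            "subclone with falsely elevated mutation burden; quantitative burden "
            "unreliable, mutational profile usually still usable"
        )
        verdict = "polyclonal_suspect"
    else:
        note = "VAF distribution consistent with a single-cell-derived subclone"
        verdict = "clonal"
    return ClonalityReport(sample_id, exp, mean, int(vafs.size), verdict, p, note)


@dataclass
class SharedVariantMatrix:
    """Symmetric matrix of pairwise shared variant counts; diagonal = burdens."""

    sample_ids: List[str]
    shared: np.ndarray

    def __post_init__(self):
        self.shared = np.asarray(self.shared, dtype=np.int64)
        n = len(self.sample_ids)
        if self.shared.shape != (n, n):
            raise InvalidInputError("shared matrix shape does not match sample ids")

    @property
    def burdens(self) -> np.ndarray:
        return np.diag(self.shared)

    def _i(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise MissingSampleError(sample_id) from None

    def pair(self, a: str, b: str) -> int:
        return int(self.shared[self._i(a), self._i(b)])

    def containment(self, parent: str, child: str) -> float:
        """Fraction of the parent's mutations present in the child."""
        pb = int(self.shared[self._i(parent), self._i(parent)])
        return self.pair(parent, child) / pb if pb else 0.0

    def sibling_fraction(self, a: str, b: str) -> float:
        """Shared count over the smaller of the two burdens."""
        ia, ib = self._i(a), self._i(b)
        m = min(self.shared[ia, ia], self.shared[ib, ib])
        return self.shared[ia, ib] / m if m else 0.0


def shared_variant_matrix(
    variants_by_sample: Mapping[str, Set[tuple]],
) -> SharedVariantMatrix:
    """Pairwise shared-variant counts over (chrom, pos, ref, alt) keys."""
    ids = list(variants_by_sample)
    sets = [frozenset(variants_by_sample[s]) for s in ids]
    n = len(ids)
    m = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        m[i, i] = len(sets[i])
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = len(sets[i] & sets[j])
    return SharedVariantMatrix(ids, m)


@dataclass
class LineageManifest:
    """Declared family structure and condition labels of an experiment."""

    grandparent_id: str
    parents: List[str]
    children: Dict[str, List[str]]  # parent id -> subclone ids
    condition: Dict[str, str]  # sample id -> "control" | "experimental:<name>"

    def __post_init__(self):
        ids: List[str] = [self.grandparent_id, *self.parents]
        declared_parent: Dict[str, str] = {}
        for p, subs in self.children.items():
            if p not in self.parents:
                raise InvalidInputError(f"children listed under undeclared parent {p!r}")
            for s in subs:
                if s in declared_parent:
                    raise InvalidInputError(f"subclone {s!r} has two declared parents")
                declared_parent[s] = p
                ids.append(s)
        if len(set(ids)) != len(ids):
            raise InvalidInputError("sample ids in manifest are not unique")
        self._declared_parent = declared_parent

    @property
    def subclones(self) -> List[str]:
        return [s for p in self.parents for s in self.children.get(p, [])]

    def parent_of(self, subclone: str) -> str:
        return self._declared_parent[subclone]

    def control_samples(self) -> List[str]:
        return [s for s in self.subclones if self.condition.get(s) == "control"]

    def experimental_samples(self, name: Optional[str] = None) -> List[str]:
        out = []
        for s in self.subclones:
            cond = self.condition.get(s, "")
            if cond.startswith("experimental"):
                if name is None or cond == f"experimental:{name}":
                    out.append(s)
        return out

    def conditions(self) -> List[str]:
        names = []
        for s in self.subclones:
            cond = self.condition.get(s, "")
            if cond.startswith("experimental:"):
                n = cond.split(":", 1)[1]
                if n not in names:
                    names.append(n)
        return names


@dataclass
class LineageScenario:
    parent_id: str
    scenario: str  # "consistent" | "wrong_parent" | "mixed_parental"
    containment: Dict[str, float]  # subclone -> fraction of parent's mutations
    private: Dict[str, int]  # subclone -> private mutation count
    sibling_groups: List[List[str]]
    note: str = ""


def _sibling_groups(
    matrix: SharedVariantMatrix, siblings: Sequence[str], theta_s: float
) -> List[List[str]]:
    """Single-linkage lineage groups among declared siblings.

    Pairwise sharing is normalized by the *largest* pairwise shared count
    in the family before cutting at ``theta_s``. Same-lineage siblings
    share the full parental set while cross-lineage pairs share ~none,
    so the relative pattern separates lineages regardless of how many
    condition-private (e.g. treatment) mutations inflate the burdens —
    an absolute shared/burden cut would split genuinely related, heavily
    mutagenized siblings. With no sharing at all every sibling is its
    own group.
    """
    k = len(siblings)
    if k <= 1:
        return [list(siblings)]
    shared = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            shared[i, j] = shared[j, i] = matrix.pair(siblings[i], siblings[j])
    peak = shared.max()
    if peak == 0:
        return [[s] for s in siblings]
    dist = 1.0 - shared / peak
    condensed = dist[np.triu_indices(k, 1)]
    link = cluster.hierarchy.linkage(condensed, method="single")
    assign = cluster.hierarchy.fcluster(link, t=1.0 - theta_s, criterion="distance")
    groups: Dict[int, List[str]] = {}
    for s, g in zip(siblings, assign):
        groups.setdefault(int(g), []).append(s)
    return sorted(groups.values(), key=lambda g: (-len(g), g))


def check_lineage(
    matrix: SharedVariantMatrix,
    manifest: LineageManifest,
    theta_p: float = THETA_PARENT,
    theta_s: float = THETA_SIBLING,
) -> Dict[str, LineageScenario]:
    """Classify each declared parent's family into one of three scenarios.

    ``consistent``: every declared subclone contains at least ``theta_p``
    of the parent's mutations and has at least one private mutation.
    ``wrong_parent``: the siblings mutually share at least ``theta_s`` of
    the smaller burden but none contains the declared parent — the wrong
    parental clone was sequenced (or the label is wrong).
    ``mixed_parental``: single-linkage grouping of the siblings at the
    sharing cut splits them into two or more lineages.
    """
    for s in (manifest.grandparent_id, *manifest.parents, *manifest.subclones):
        if s not in matrix.sample_ids:
            raise MissingSampleError(f"manifest sample {s!r} absent from matrix")
    out: Dict[str, LineageScenario] = {}
    for parent in manifest.parents:
        siblings = list(manifest.children.get(parent, []))
        containment = {s: matrix.containment(parent, s) for s in siblings}
        private = {
            s: int(matrix.pair(s, s) - matrix.pair(parent, s)) for s in siblings
        }
        groups = _sibling_groups(matrix, siblings, theta_s)
        any_sharing = any(
            matrix.pair(a, b) > 0
            for i, a in enumerate(siblings)
            for b in siblings[i + 1 :]
        )
        all_contained = all(c >= theta_p for c in containment.values())
        none_contained = all(c < theta_p for c in containment.values())
        has_private = all(p >= 1 for p in private.values())

        if all_contained and has_private and len(groups) == 1:
            scenario, note = "consistent", "subclones share their declared parent and each carries private mutations"
        elif none_contained and len(groups) == 1 and any_sharing and siblings:
            scenario, note = (
                "wrong_parent",
                "subclones form one lineage but none contains the sequenced parent: "
                "likely an incorrect parental clone was sequenced",
            )
        elif len(groups) >= 2:
            scenario, note = (
                "mixed_parental",
                "subclones split into multiple sharing groups: derived from a mixed "
                "parental population",
            )
        elif none_contained:
            scenario, note = "wrong_parent", "no subclone contains the sequenced parent"
        else:
            scenario, note = (
                "consistent",
                "sharing pattern broadly matches the declared lineage",
            )
        out[parent] = LineageScenario(parent, scenario, containment, private, groups, note)
    return out


@dataclass
class QCReport:
    """Combined lineage + clonality screen of a whole experiment."""

    scenario: str  # worst finding: clean | wrong_parent | mixed_parental | polyclonal
    lineage: Dict[str, "LineageScenario"]
    clonality: Dict[str, ClonalityReport]
    notes: List[str] = field(default_factory=list)


def screen_experiment(
    records_by_sample: Mapping[str, Sequence[MutationRecord]],
    manifest: LineageManifest,
    ploidy: int = 2,
    theta_p: float = THETA_PARENT,
    theta_s: float = THETA_SIBLING,
) -> QCReport:
    """Run the full QC battery and name the dominant failure scenario.

    Lineage findings (wrong parent, mixed parental population) take
    precedence over clonality findings, since they invalidate the family
    structure itself. Clonality is assessed on each subclone's *private*
    mutations (those absent from its declared parent): inherited
    mutations are clonal in every cell even of a polyclonal subclone, so
    including them would mask the VAF shift. Subclones with too few
    private mutations for a verdict are noted, not flagged. Copy-number
    stability and driver screening are not assessed here.
    """
    sets = {
        s: {r.key for r in recs} for s, recs in records_by_sample.items()
    }
    matrix = shared_variant_matrix(sets)
    lineage = check_lineage(matrix, manifest, theta_p=theta_p, theta_s=theta_s)

    clonality: Dict[str, ClonalityReport] = {}
    notes: List[str] = ["copy-number stability: not assessed",
                        "driver mutations: not assessed"]
    for sub in manifest.subclones:
        parent = manifest.parent_of(sub)
        parent_keys = sets.get(parent, set())
        private = [
            r for r in records_by_sample.get(sub, []) if r.key not in parent_keys
        ]
        vafs = [r.vaf for r in private]
        depths = [r.depth for r in private]
        try:
            clonality[sub] = clonality_check(
                vafs, depths, ploidy=ploidy, sample_id=sub
            )
        except InsufficientDataError as exc:
            notes.append(f"{sub}: {exc}")

    scenario = "clean"
    if any(l.scenario == "wrong_parent" for l in lineage.values()):
        scenario = "wrong_parent"
    elif any(l.scenario == "mixed_parental" for l in lineage.values()):
        scenario = "mixed_parental"
    elif any(c.verdict == "polyclonal_suspect" for c in clonality.values()):
        scenario = "polyclonal"
    return QCReport(scenario, lineage, clonality, notes)


def on_target_edit_check(
    records: Iterable[MutationRecord],
    chrom: str,
    start1: int,
    end1: int,
) -> Tuple[str, List[MutationRecord]]:
    """Check for short indels inside a gRNA target window (1-based, closed).

    Returns ``("edited", hits)`` when at least one insertion/deletion
    overlaps the window, else ``("not_edited", [])``.
    """
    if start1 < 1 or end1 < start1:
        raise InvalidInputError(f"malformed interval {chrom}:{start1}-{end1}")
    if end1 - start1 + 1 > 10_000:
        raise InvalidInputError("target window longer than 10 kb")
    hits = []
    for rec in records:
        if rec.mclass not in ("INS", "DEL") or rec.chrom != chrom:
            continue
        span = len(rec.ref) if rec.mclass == "DEL" else 1
        rec_start, rec_end = rec.pos, rec.pos + span - 1
        if rec_start <= end1 and rec_end >= start1:
            hits.append(rec)
    return ("edited", hits) if hits else ("not_edited", hits)
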