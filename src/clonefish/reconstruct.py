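"""Clone inference: CCF clustering, tree enumeration, classification.

Aberrations whose CCF trajectories move together are grouped into
clones; all parent assignments satisfying the pigeonhole (subset-sum)
constraints of tumor phylogenies are enumerated; each admissible tree is
classified as linear, branched or neutral evolution. When a CNV/SNV
overlap is ambiguous, the reconstruction branches per surviving case --
alternatives are emitted and labeled, never auto-selected.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .ccf import CcfEstimate, CcfSource, CopyContext, ccf_from_counts, \
    ccf_from_log2ratio, ccf_from_vaf
from .cytobands import GENE_LOCI, parse_band
from .iomodel import ClinicalStatus, Direction, Kind, PatientBundle, \
    infer_der_losses
from .overlap import CnvType, OverlapCase, enumerate_overlap_cases, \
    _estimate_from as _overlap_estimate

__all__ = [
    "Clone", "CloneTree", "InfeasibleTreeError", "cluster_aberrations",
    "build_clone_trees", "classify_evolution", "reconstruct_patient",
    "trees_to_json",
]

PRESENCE_EPS = 0.005     # CCF below this counts as 'absent'
ABSENT_SE = 0.0255       # Gaussian SE assigned to an unobserved (0) CCF
DEFAULT_TOL = 0.10       # clustering tolerance on CCF
DEFAULT_DELTA = 0.05     # nesting slack on subset sums
MAX_TREES = 10_000       # deterministic cap for large instances


class InfeasibleTreeError(ValueError):
    """No parent assignment satisfies the nesting constraints."""


@dataclass
class Clone:
    id: str
    aberration_ids: FrozenSet[str]
    ccf_by_timepoint: Dict[int, float]
    se_by_timepoint: Dict[int, float] = field(default_factory=dict)

    def ccf(self, t: int) -> float:
        return self.ccf_by_timepoint.get(t, 0.0)

    @property
    def first_timepoint(self) -> int:
        present = [t for t, v in sorted(self.ccf_by_timepoint.items())
                   if v > PRESENCE_EPS]
        return present[0] if present else len(self.ccf_by_timepoint)


@dataclass
class CloneTree:
    clones: List[Clone]
    parent: Dict[str, Optional[str]]       # clone id -> parent id or None
    pattern: str = ""                      # linear | branched | neutral
    alternatives_rank: int = 0
    label: str = ""                        # which overlap case produced it

    def children(self, clone_id: Optional[str]) -> List[Clone]:
        return [c for c in self.clones if self.parent[c.id] == clone_id]

    def n_roots(self) -> int:
        return sum(1 for c in self.clones if self.parent[c.id] is None)


# --------------------------------------------------------------------------
# Clustering
# --------------------------------------------------------------------------

def _traj(estimates: Dict[int, CcfEstimate], t: int) -> Tuple[float, float, float]:
    est = estimates.get(t)
    if est is None:
        return 0.0, 0.0, 2 * 1.96 * ABSENT_SE
    return est.ccf, est.ci_low, est.ci_high


def _compatible(a: Dict[int, CcfEstimate], b: Dict[int, CcfEstimate],
                n_tp: int, tol: float) -> bool:
    """Trajectories agree within tol at every time point, or their 95%
    intervals overlap there (whichever is more permissive)."""
    for t in range(n_tp):
        ca, loa, hia = _traj(a, t)
        cb, lob, hib = _traj(b, t)
        if abs(ca - cb) <= tol:
            continue
        if loa <= hib and lob <= hia:
            continue
        return False
    return True


def cluster_aberrations(estimates: Dict[str, Dict[int, CcfEstimate]],
                        n_timepoints: int,
                        tol: float = DEFAULT_TOL) -> List[Clone]:
    """Group aberrations into clones by CCF trajectory agreement.

    Deterministic greedy agglomeration over aberrations ordered by
    (first appearance, descending peak CCF, id); an aberration joins the
    first clone it is compatible with at every member and every time
    point. Clone CCF per time point is the precision-weighted mean of
    its members (unobserved members enter as 0 with a broad band).
    """
    def first_tp(abid: str) -> int:
        pres = [t for t, e in sorted(estimates[abid].items())
                if e.ccf > PRESENCE_EPS]
        return pres[0] if pres else n_timepoints

    def peak(abid: str) -> float:
        return max((e.ccf for e in estimates[abid].values()), default=0.0)

    order = sorted(estimates, key=lambda a: (first_tp(a), -peak(a), a))
    groups: List[List[str]] = []
    for abid in order:
        for grp in groups:
            if all(_compatible(estimates[abid], estimates[m], n_timepoints,
                               tol) for m in grp):
                grp.append(abid)
                break
        else:
            groups.append([abid])

    clones = []
    for i, grp in enumerate(groups):
        ccf_t, se_t = {}, {}
        for t in range(n_timepoints):
            wsum = vsum = 0.0
            for m in grp:
                est = estimates[m].get(t)
                v, se = (est.ccf, est.se) if est else (0.0, ABSENT_SE)
                w = 1.0 / se ** 2
                wsum += w
                vsum += w * v
            ccf_t[t] = vsum / wsum
            se_t[t] = wsum ** -0.5
        clones.append(Clone(id=f"C{i + 1}", aberration_ids=frozenset(grp),
                            ccf_by_timepoint=ccf_t, se_by_timepoint=se_t))
    return clones


# --------------------------------------------------------------------------
# Tree enumeration
# --------------------------------------------------------------------------

LineageConstraint = Tuple[str, str, str]  # (relation, aberration_a, aberration_b)


def _is_ancestor(parent: Dict[str, Optional[str]], anc: str, desc: str) -> bool:
    node = parent[desc]
    while node is not None:
        if node == anc:
            return True
        node = parent[node]
    return False


def _violated(clones: Sequence[Clone], parent: Dict[str, Optional[str]],
              delta: float,
              constraints: Sequence[Tuple[str, str, str]]) -> Optional[str]:
    """First violated admissibility condition, or None."""
    by_id = {c.id: c for c in clones}
    # acyclic
    for c in clones:
        seen = set()
        node = c.id
        while node is not None:
            if node in seen:
                return f"cycle through {node}"
            seen.add(node)
            node = parent[node]
    # a child cannot appear before its parent
    for c in clones:
        p = parent[c.id]
        if p is not None and c.first_timepoint < by_id[p].first_timepoint:
            return f"{c.id} appears before its parent {p}"
    # subset sums at every time point
    n_tp = max(len(c.ccf_by_timepoint) for c in clones)
    for t in range(n_tp):
        root_sum = 0.0
        kids_sum: Dict[str, float] = {c.id: 0.0 for c in clones}
        for c in clones:
            p = parent[c.id]
            if p is None:
                root_sum += c.ccf(t)
            else:
                kids_sum[p] += c.ccf(t)
        if root_sum > 1.0 + delta:
            return f"root clones sum to {root_sum:.3f} > 1 at t={t}"
        for cid, s in kids_sum.items():
            if s > by_id[cid].ccf(t) + delta:
                return (f"children of {cid} sum to {s:.3f} > "
                        f"{by_id[cid].ccf(t):.3f} at t={t}")
    # lineage constraints from overlap scenarios
    clone_of = {a: c.id for c in clones for a in c.aberration_ids}
    for rel, a, b in constraints:
        ca, cb = clone_of.get(a), clone_of.get(b)
        if ca is None or cb is None:
            continue
        if rel == "ancestor":
            if ca != cb and not _is_ancestor(parent, ca, cb):
                return f"{a} must be ancestral to {b}"
        elif rel == "unrelated":
            if ca == cb or _is_ancestor(parent, ca, cb) \
                    or _is_ancestor(parent, cb, ca):
                return f"{a} and {b} must be in unrelated lineages"
    return None


def build_clone_trees(clones: Sequence[Clone], delta: float = DEFAULT_DELTA,
                      constraints: Sequence[LineageConstraint] = (),
                      max_trees: int = MAX_TREES) -> List[CloneTree]:
    """Enumerate every admissible parent assignment.

    Admissible: acyclic; a child first appears no earlier than its
    parent; at every time point the children of a clone sum to at most
    its CCF + delta and root clones sum to at most 1 + delta; lineage
    constraints hold. Output is deterministically ordered: fewest roots
    first, then lexicographic on the parent vector. Exhaustive for small
    clone counts; capped at ``max_trees`` results.

    Raises :class:`InfeasibleTreeError` (reporting the first violated
    constraint) when no tree is admissible.
    """
    clones = sorted(clones, key=lambda c: (
        c.first_timepoint, -max(c.ccf_by_timepoint.values(), default=0.0),
        c.id))
    ids = [c.id for c in clones]
    n = len(ids)
    if n == 0:
        raise InfeasibleTreeError("no clones to place in a tree")

    # per-clone candidate parents from pairwise necessary conditions
    by_id = {c.id: c for c in clones}
    n_tp = max(len(c.ccf_by_timepoint) for c in clones)
    candidates: List[List[Optional[str]]] = []
    for c in clones:
        cand: List[Optional[str]] = [None]
        for p in clones:
            if p.id == c.id:
                continue
            if c.first_timepoint < p.first_timepoint:
                continue
            if all(c.ccf(t) <= p.ccf(t) + delta for t in range(n_tp)):
                cand.append(p.id)
        candidates.append(cand)

    results: List[Tuple[Tuple[int, ...], Dict[str, Optional[str]]]] = []
    first_reason: List[Optional[str]] = [None]

    for combo in itertools.product(*candidates):
        parent = dict(zip(ids, combo))
        reason = _violated(clones, parent, delta, constraints)
        if reason is None:
            key = tuple(0 if p is None else ids.index(p) + 1 for p in combo)
            results.append((key, parent))
            if len(results) >= max_trees:
                break
        elif first_reason[0] is None:
            first_reason[0] = reason

    if not results:
        raise InfeasibleTreeError(
            first_reason[0] or "no admissible parent assignment")

    # order: fewest roots first, then lexicographic parent vector
    results.sort(key=lambda item: (sum(1 for k in item[0] if k == 0), item[0]))
    trees = []
    for rank, (_key, parent) in enumerate(results):
        trees.append(CloneTree(clones=list(clones), parent=parent,
                               alternatives_rank=rank))
    for tree in trees:
        tree.pattern = classify_evolution(tree)
    return trees


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_evolution(tree, k_neutral: int = 4,
                       dominance: float = 0.5) -> str:
    """Classify a clone tree as linear, branched or neutral evolution.

    linear: every clone (and the germline root) has at most one child.
    branched: some clone spawns two or more subclones.
    neutral: an extreme of branching -- at some time point at least
    ``k_neutral`` sibling subclones coexist and none of them reaches
    the ``dominance`` fraction.

    Accepts a :class:`CloneTree` or a plain list of
    (id, parent, ccf_list) triples.
    """
    if isinstance(tree, CloneTree):
        triples = [(c.id, tree.parent[c.id],
                    [c.ccf(t) for t in range(
                        max(len(c.ccf_by_timepoint) for c in tree.clones))])
                   for c in tree.clones]
    else:
        triples = [(cid, parent, list(ccfs)) for cid, parent, ccfs in tree]

    n_tp = len(triples[0][2]) if triples else 0
    sibling_groups: Dict[Optional[str], List[List[float]]] = {}
    for _cid, parent, ccfs in triples:
        sibling_groups.setdefault(parent, []).append(ccfs)

    for sibs in sibling_groups.values():
        for t in range(n_tp):
            live = [s[t] for s in sibs if s[t] > PRESENCE_EPS]
            if len(live) >= k_neutral and max(live) < dominance:
                return "neutral"
    if all(len(sibs) <= 1 for sibs in sibling_groups.values()):
        return "linear"
    return "branched"


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

def _combine(parts: List[CcfEstimate], source: CcfSource) -> CcfEstimate:
    if len(parts) == 1:
        return parts[0]
    wsum = sum(1.0 / p.se ** 2 for p in parts)
    mean = sum(p.ccf / p.se ** 2 for p in parts) / wsum
    se = wsum ** -0.5
    flags = frozenset().union(*(p.flags for p in parts))
    return CcfEstimate(ccf=mean, ci_low=max(0.0, mean - 1.96 * se),
                       ci_high=min(1.0, mean + 1.96 * se), source=source,
                       flags=flags)


def estimate_ccfs(bundle: PatientBundle,
                  infer_der: bool = True
                  ) -> Dict[str, Dict[int, CcfEstimate]]:
    """Per-aberration, per-time-point CCF from the best available
    evidence: VAF for SNVs/indels (hemizygous on X/Y in males), metaphase
    and FISH counts for karyotype-visible events (precision-weighted when
    both exist), array-CGH only where nothing else saw the event.
    Remission time points with no detected aberrations are zeroed.
    Companion losses implied by unbalanced derivative chromosomes share
    their source aberration's estimates.
    """
    est: Dict[str, Dict[int, List[CcfEstimate]]] = {}

    def add(abid: str, t: int, e: CcfEstimate) -> None:
        est.setdefault(abid, {}).setdefault(t, []).append(e)

    male = (bundle.sex or "").lower().startswith("m")
    for obs in bundle.variant_obs:
        ab = bundle.aberrations[obs.aberration_id]
        chrom = GENE_LOCI.get(ab.gene, (None, None))[0]
        ctx = CopyContext.HEMIZYGOUS if (male and chrom in ("X", "Y")) \
            else CopyContext.AUTOSOMAL_HET
        add(obs.aberration_id, obs.timepoint_index,
            ccf_from_vaf(obs.vaf, ctx, obs.depth, obs.alt_reads))

    # metaphase counts: an aberration's carriers = all clone lines listing it
    karyo_by_tp: Dict[int, List] = {}
    for kobs in bundle.karyotype_obs:
        karyo_by_tp.setdefault(kobs.timepoint_index, []).append(kobs)
    for t, rows in karyo_by_tp.items():
        totals = {r.metaphases_total for r in rows}
        if len(totals) > 1:
            raise ValueError(
                f"karyotype rows at t={t} disagree on metaphases_total")
        total = totals.pop()
        per_ab: Dict[str, int] = {}
        for r in rows:
            for abid in r.aberration_ids:
                per_ab[abid] = per_ab.get(abid, 0) + r.metaphases_with
        for abid, k in per_ab.items():
            if k > total:
                raise ValueError(
                    f"clone lines at t={t} overlap: {abid} in >total cells")
            add(abid, t, ccf_from_counts(k, total, CcfSource.METAPHASE))

    for fobs in bundle.fish_obs:
        if fobs.aberration_id is not None:
            add(fobs.aberration_id, fobs.timepoint_index,
                ccf_from_counts(fobs.nuclei_with, fobs.nuclei_total,
                                CcfSource.FISH))

    combined: Dict[str, Dict[int, CcfEstimate]] = {}
    for abid, per_tp in est.items():
        combined[abid] = {t: _combine(parts, parts[0].source)
                          for t, parts in per_tp.items()}

    # CGH fills in only where counting methods saw nothing
    for seg in bundle.cgh_segments:
        if seg.aberration_id is None:
            continue
        slot = combined.setdefault(seg.aberration_id, {})
        if seg.timepoint_index not in slot:
            ab = bundle.aberrations[seg.aberration_id]
            slot[seg.timepoint_index] = ccf_from_log2ratio(
                seg.log2_ratio, ab.cnv_direction)

    # remission time points with nothing detected force CCF = 0
    for tp in bundle.timepoints:
        if tp.clinical_status != ClinicalStatus.REMISSION:
            continue
        detected = any(t == tp.index and e.ccf > PRESENCE_EPS
                       for per_tp in combined.values()
                       for t, e in per_tp.items())
        if not detected:
            for per_tp in combined.values():
                per_tp.pop(tp.index, None)

    # unbalanced der(N)t(A;B) implies a terminal loss on N, carried by
    # the same cells as the derivative chromosome itself
    if infer_der:
        for loss in infer_der_losses(list(bundle.aberrations.values())):
            if loss.inferred_from in combined:
                bundle.aberrations.setdefault(loss.id, loss)
                combined[loss.id] = dict(combined[loss.inferred_from])
    return combined


def _overlap_pairs(bundle: PatientBundle,
                   estimates: Dict[str, Dict[int, CcfEstimate]]
                   ) -> List[Tuple[str, str, CnvType]]:
    """(snv_id, cnv_id, cnv_type) for every variant under a CNV."""
    pairs = []
    for abid, ab in sorted(bundle.aberrations.items()):
        if ab.kind not in (Kind.SNV, Kind.INDEL) or abid not in estimates:
            continue
        locus = GENE_LOCI.get(ab.gene)
        if locus is None:
            continue
        chrom, band = locus
        region = parse_band(band)
        for cid, cnv in sorted(bundle.aberrations.items()):
            if cnv.kind != Kind.CNV or cid not in estimates:
                continue
            if cnv.chrom != chrom or cnv.region is None:
                continue
            if cnv.region.overlaps(region):
                ctype = CnvType.DELETION \
                    if cnv.cnv_direction == Direction.LOSS \
                    else CnvType.DUPLICATION
                pairs.append((abid, cid, ctype))
    return pairs


def _surviving_configs(snv_est: Dict[int, CcfEstimate],
                       cnv_est: Dict[int, CcfEstimate],
                       bundle_vafs: Dict[int, float],
                       cnv_type: CnvType, eps: float
                       ) -> List[Tuple[Tuple[int, int], Dict[int, OverlapCase]]]:
    """Scenario/cnv_value configs feasible at every time point where the
    CNV is present; each returned with its per-time-point solved case."""
    cvs = [(1, 1), (2, 0), (2, 1), (3, 1)] if cnv_type == CnvType.DELETION \
        else [(1, 1), (2, 1), (2, 2), (3, 1)]
    survivors = []
    for scenario, cv in cvs:
        cases: Dict[int, OverlapCase] = {}
        ok = True
        for t, vaf in sorted(bundle_vafs.items()):
            c_cnv = cnv_est.get(t)
            if c_cnv is None or c_cnv.ccf <= PRESENCE_EPS:
                continue
            all_cases = enumerate_overlap_cases(vaf, c_cnv.ccf, cnv_type, eps)
            case = next(c for c in all_cases
                        if c.scenario == scenario and c.cnv_value == cv)
            if not case.feasible:
                ok = False
                break
            cases[t] = case
        if ok and cases:
            survivors.append(((scenario, cv), cases))
    return survivors


_SCENARIO_RELATION = {1: "cnv_first", 2: "snv_first", 3: "independent"}


def reconstruct_patient(bundle: PatientBundle, tol: float = DEFAULT_TOL,
                        delta: float = DEFAULT_DELTA, eps: float = 0.05,
                        infer_der: bool = True,
                        k_neutral: int = 4) -> List[CloneTree]:
    """Full pipeline: CCF estimation -> overlap resolution (branching the
    reconstruction per surviving case) -> clustering -> tree enumeration
    -> classification. Returns all alternatives, deterministically
    ordered and ranked."""
    estimates = estimate_ccfs(bundle, infer_der=infer_der)
    if not estimates:
        raise InfeasibleTreeError("no aberrations with evidence")

    vafs_by_snv: Dict[str, Dict[int, float]] = {}
    for obs in bundle.variant_obs:
        vafs_by_snv.setdefault(obs.aberration_id, {})[
            obs.timepoint_index] = obs.vaf

    pairs = _overlap_pairs(bundle, estimates)
    branch_space = []
    for snv_id, cnv_id, ctype in pairs:
        configs = _surviving_configs(
            estimates[snv_id], estimates[cnv_id],
            vafs_by_snv.get(snv_id, {}), ctype, eps)
        if configs:
            branch_space.append((snv_id, cnv_id, configs))

    n_tp = len(bundle.timepoints)
    alternatives: List[CloneTree] = []
    seen = set()

    for combo in itertools.product(*(c for _s, _c, c in branch_space)) \
            if branch_space else [()]:
        branch_est = {a: dict(per) for a, per in estimates.items()}
        constraints: List[LineageConstraint] = []
        labels = []
        for (snv_id, cnv_id, cfgs), ((scenario, cv), cases) in zip(
                branch_space, combo):
            ambiguous = len(cfgs) > 1
            for t, case in cases.items():
                branch_est[snv_id][t] = _overlap_estimate(
                    case.ccf_snv, case.w + case.y, ambiguous)
            labels.append(f"{snv_id}|{cnv_id}:scenario{scenario}"
                          f"/cnv_value={cv}")
            rel = _SCENARIO_RELATION[scenario]
            if rel == "cnv_first":
                constraints.append(("ancestor", cnv_id, snv_id))
            elif rel == "snv_first":
                constraints.append(("ancestor", snv_id, cnv_id))
            else:
                constraints.append(("unrelated", snv_id, cnv_id))

        clones = cluster_aberrations(branch_est, n_tp, tol)
        clones = [c for c in clones
                  if any(v > PRESENCE_EPS for v in c.ccf_by_timepoint.values())]
        if not clones:
            continue
        try:
            trees = build_clone_trees(clones, delta, constraints)
        except InfeasibleTreeError:
            if not branch_space:
                raise
            continue
        for tree in trees:
            tree.label = "; ".join(labels) if labels else "unique"
            key = (tuple(sorted((c.id, tuple(sorted(c.aberration_ids)),
                                 tuple(round(c.ccf(t), 6)
                                       for t in range(n_tp)))
                                for c in tree.clones)),
                   tuple(sorted(tree.parent.items())))
            if key in seen:
                continue
            seen.add(key)
            alternatives.append(tree)

    if not alternatives:
        raise InfeasibleTreeError(
            "every overlap branch yields an inadmissible tree")
    for rank, tree in enumerate(alternatives):
        tree.alternatives_rank = rank
    return alternatives


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def trees_to_json(bundle_or_patient, timepoints: Sequence[str],
                  trees: Sequence[CloneTree]) -> dict:
    patient = getattr(bundle_or_patient, "patient", bundle_or_patient)
    n_tp = len(timepoints)
    return {
        "patient": patient,
        "timepoints": list(timepoints),
        "alternatives": [{
            "rank": t.alternatives_rank,
            "pattern": t.pattern,
            "label": t.label,
            "clones": [{
                "id": c.id,
                "parent": t.parent[c.id],
                "aberrations": sorted(c.aberration_ids),
                "ccf": [round(c.ccf(i), 6) for i in range(n_tp)],
            } for c in t.clones],
        } for t in trees],
    }


def save_trees(path, bundle, trees: Sequence[CloneTree]) -> None:
    doc = trees_to_json(bundle, [tp.label for tp in bundle.timepoints], trees)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
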