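"""Synthetic-data generator and brute-force oracle.

A clone tree with per-time-point fractions is realized as an explicit
:class:`CellPopulation` (clone -> cell fraction, per-locus allele copy
counts). From the population the exact allele frequency of any locus is
a direct sum -- the independent oracle for the overlap equations -- and
noisy multi-modal observations (panel VAFs, metaphase counts, FISH
nuclei, array-CGH log2 ratios) are drawn from it, writing the same TSV
bundle format the readers consume plus a ``truth.json`` in the
reconstruction output schema.

Random streams are split per modality from one master seed, so adding a
modality does not shift the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .cytobands import band_to_coords
from .iomodel import Direction, Kind, parse_iscn
from .overlap import CnvType

__all__ = [
    "CellPopulation", "SimClone", "exact_vaf",
    "population_from_overlap_case", "simulate_observations",
]


@dataclass
class CellPopulation:
    """Explicit cell mixture: clone fractions plus per-locus genotypes.

    ``genotype[(clone_id, locus)] = (mutant_copies, total_copies)``.
    """

    clones: Dict[str, float]
    genotype: Dict[Tuple[str, str], Tuple[int, int]]

    def __post_init__(self) -> None:
        total = sum(self.clones.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions sum to {total}, not 1")
        for (cid, locus), (mut, tot) in self.genotype.items():
            if tot < 1 or mut < 0 or mut > tot:
                raise ValueError(f"invalid genotype for ({cid}, {locus})")


def exact_vaf(pop: CellPopulation, locus: str) -> float:
    """Population allele frequency: sum(f*mut) / sum(f*total)."""
    num = den = 0.0
    for cid, frac in pop.clones.items():
        if (cid, locus) not in pop.genotype:
            raise KeyError(f"locus {locus!r} not genotyped in clone {cid!r}")
        mut, tot = pop.genotype[(cid, locus)]
        num += frac * mut
        den += frac * tot
    if den == 0.0:
        raise ValueError(f"zero total copies at locus {locus!r}")
    return num / den


def population_from_overlap_case(w: float, x: float, y: float, z: float,
                                 cnv_type: CnvType, cnv_value: int,
                                 locus: str = "L") -> CellPopulation:
    """Realize the four cell classes of a CNV/SNV overlap configuration.

    CNV-bearing cells (w, x) carry 1 copy for a deletion and 3 for a
    single-copy duplication; ``cnv_value`` mutant copies in the w class.
    """
    tot_cnv = 1 if CnvType(cnv_type) == CnvType.DELETION else 3
    if not 0 <= cnv_value <= tot_cnv:
        raise ValueError("cnv_value exceeds copies present")
    clones = {"w": w, "x": x, "y": y, "z": z}
    genotype = {
        ("w", locus): (cnv_value, tot_cnv),
        ("x", locus): (0, tot_cnv),
        ("y", locus): (1, 2),
        ("z", locus): (0, 2),
    }
    return CellPopulation(clones=clones, genotype=genotype)


# --------------------------------------------------------------------------
# Tree-over-time simulation
# --------------------------------------------------------------------------

@dataclass
class SimClone:
    """Truth clone: aberrations plus a CCF trajectory (cells carrying the
    clone's aberrations, descendants included)."""

    id: str
    parent: Optional[str]                 # None = arises from normal cells
    ccf: List[float]                      # one fraction per time point
    snv_genes: List[str] = field(default_factory=list)
    cnv_tokens: List[str] = field(default_factory=list)
    sv_tokens: List[str] = field(default_factory=list)

    @property
    def cyto_tokens(self) -> List[str]:
        return self.cnv_tokens + self.sv_tokens

    def snv_ids(self) -> List[str]:
        return [f"{g}:c.100A>G" for g in self.snv_genes]

    def aberration_ids(self) -> List[str]:
        return self.snv_ids() + self.cyto_tokens


def _check_tree(clones: Sequence[SimClone]) -> Dict[str, SimClone]:
    by_id = {c.id: c for c in clones}
    n_tp = len(clones[0].ccf)
    for c in clones:
        if len(c.ccf) != n_tp:
            raise ValueError("all clones need the same number of time points")
        if c.parent is not None and c.parent not in by_id:
            raise ValueError(f"unknown parent {c.parent!r}")
    for t in range(n_tp):
        for c in clones:
            kids = sum(k.ccf[t] for k in clones if k.parent == c.id)
            if kids > c.ccf[t] + 1e-9:
                raise ValueError(f"children of {c.id} exceed parent at t={t}")
        roots = sum(c.ccf[t] for c in clones if c.parent is None)
        if roots > 1.0 + 1e-9:
            raise ValueError(f"root clones exceed 1 at t={t}")
    return by_id


def _ancestry(clone: SimClone, by_id: Dict[str, SimClone]) -> List[SimClone]:
    chain = [clone]
    while chain[-1].parent is not None:
        chain.append(by_id[chain[-1].parent])
    return chain


def _exclusive_fractions(clones: Sequence[SimClone], t: int) -> Dict[str, float]:
    """clone -> fraction of cells whose most-derived clone is that clone;
    '' keys the normal (aberration-free) compartment."""
    out = {}
    for c in clones:
        kids = sum(k.ccf[t] for k in clones if k.parent == c.id)
        out[c.id] = max(0.0, c.ccf[t] - kids)
    roots = sum(c.ccf[t] for c in clones if c.parent is None)
    out[""] = max(0.0, 1.0 - roots)
    return out


def population_at(clones: Sequence[SimClone], t: int) -> CellPopulation:
    """Explicit population at time point t (heterozygous SNVs, loci named
    by gene; CNV tokens do not overlap the simulated SNV loci)."""
    by_id = _check_tree(clones)
    excl = _exclusive_fractions(clones, t)
    loci = sorted({g for c in clones for g in c.snv_genes})
    genotype = {}
    for cid in excl:
        carried = set()
        if cid:
            for anc in _ancestry(by_id[cid], by_id):
                carried.update(anc.snv_genes)
        for g in loci:
            genotype[(cid, g)] = (1, 2) if g in carried else (0, 2)
    return CellPopulation(clones=excl, genotype=genotype)


def _truth_pattern(clones: Sequence[SimClone]) -> str:
    from .reconstruct import classify_evolution  # local: avoid cycle
    return classify_evolution(
        [(c.id, c.parent, c.ccf) for c in clones])


def simulate_observations(clones: Sequence[SimClone], out_dir,
                          depth: int = 5000, n_metaphases: int = 20,
                          n_nuclei: int = 200, cgh_noise_sd: float = 0.0,
                          seed: int = 0, patient: str = "sim",
                          tp_labels: Optional[Sequence[str]] = None,
                          fish_tokens: Sequence[str] = (),
                          cgh_tokens: Sequence[str] = (),
                          exact: bool = False) -> Path:
    """Write a noisy (or, with ``exact=True``, noiseless) patient bundle.

    VAFs ~ Binomial(depth, exact_vaf)/depth; metaphases ~ Multinomial
    over the exclusive clone fractions; FISH ~ Binomial(n_nuclei,
    carrier fraction); CGH log2 ratios = forward one-copy model +
    Gaussian(0, cgh_noise_sd). Variants with zero sampled reads are not
    reported (below detection). A truth.json in the reconstruction
    schema is written alongside.
    """
    if depth <= 0 or n_metaphases <= 0 or n_nuclei <= 0:
        raise ValueError("sampling sizes must be positive")
    by_id = _check_tree(clones)
    n_tp = len(clones[0].ccf)
    if tp_labels is None:
        tp_labels = [f"t{t}" for t in range(n_tp)]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    streams = np.random.SeedSequence(seed).spawn(4)
    rng_ngs, rng_karyo, rng_fish, rng_cgh = (
        np.random.default_rng(s) for s in streams)

    ccf_of = {c.id: c.ccf for c in clones}

    # variants.tsv
    var_rows = []
    for t in range(n_tp):
        pop = population_at(clones, t)
        for c in sorted(clones, key=lambda c: c.id):
            for g in c.snv_genes:
                v = exact_vaf(pop, g)
                if exact:
                    if v > 0:
                        var_rows.append((patient, t, g, "c.100A>G", "p.?",
                                         f"{100 * v:.6f}", "", ""))
                    continue
                alt = int(rng_ngs.binomial(depth, v))
                if alt == 0:
                    continue
                var_rows.append((patient, t, g, "c.100A>G", "p.?",
                                 f"{100 * alt / depth:.6f}", depth, alt))
    _write_tsv(out_dir / "variants.tsv",
               ["patient", "timepoint", "gene", "hgvs_c", "hgvs_p",
                "vaf_percent", "depth", "alt_reads"], var_rows)

    # karyotype.tsv: one line per distinct visible token set
    karyo_rows = []
    for t in range(n_tp):
        excl = _exclusive_fractions(clones, t)
        order = [c.id for c in clones] + [""]
        fracs = np.array([excl[k] for k in order])
        if exact:
            counts = np.round(fracs * n_metaphases).astype(int)
        else:
            counts = rng_karyo.multinomial(n_metaphases, fracs / fracs.sum())
        for cid, cnt in zip(order, counts):
            if not cid or cnt == 0:
                continue
            tokens = []
            for anc in reversed(_ancestry(by_id[cid], by_id)):
                tokens.extend(anc.cyto_tokens)
            if not tokens:
                continue
            karyo_rows.append((patient, t, ",".join(tokens),
                               int(cnt), n_metaphases))
    _write_tsv(out_dir / "karyotype.tsv",
               ["patient", "timepoint", "clone_iscn", "metaphases_with",
                "metaphases_total"], karyo_rows)

    # fish.tsv: carrier fraction of the owning clone per probed token
    fish_rows = []
    token_owner = {tok: c for c in clones for tok in c.cyto_tokens}
    for t in range(n_tp):
        for tok in fish_tokens:
            owner = token_owner[tok]
            frac = ccf_of[owner.id][t]
            k = (round(frac * n_nuclei) if exact
                 else int(rng_fish.binomial(n_nuclei, frac)))
            probe = _probe_name(tok)
            fish_rows.append((patient, t, probe, k, n_nuclei))
    if fish_rows:
        _write_tsv(out_dir / "fish.tsv",
                   ["patient", "timepoint", "probe", "nuclei_with",
                    "nuclei_total"], fish_rows)

    # cgh.tsv: forward one-copy ratio model on the owning clone fraction
    cgh_rows = []
    for t in range(n_tp):
        for tok in cgh_tokens:
            owner = token_owner[tok]
            ab = parse_iscn(tok)[0]
            if ab.kind != Kind.CNV:
                raise ValueError(f"cgh token {tok!r} is not a CNV")
            f = ccf_of[owner.id][t]
            if f == 0.0:
                continue
            ratio = (2.0 - f) / 2.0 if ab.cnv_direction == Direction.LOSS \
                else (2.0 + f) / 2.0
            log2 = math.log2(ratio)
            if not exact and cgh_noise_sd > 0:
                log2 += float(rng_cgh.normal(0.0, cgh_noise_sd))
            start, end = band_to_coords(ab.chrom, ab.region)
            cgh_rows.append((ab.chrom, start, end, f"{log2:.6f}", t))
    if cgh_rows:
        _write_tsv(out_dir / "cgh.tsv",
                   ["chrom", "start", "end", "log2_ratio", "timepoint"],
                   cgh_rows)

    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump({
            "patient": patient,
            "timepoints": [{"label": lab, "status": "other"}
                           for lab in tp_labels],
        }, fh, sort_keys=False)

    truth = {
        "patient": patient,
        "timepoints": list(tp_labels),
        "alternatives": [{
            "rank": 0,
            "pattern": _truth_pattern(clones),
            "label": "truth",
            "clones": [{
                "id": c.id,
                "parent": c.parent,
                "aberrations": c.aberration_ids(),
                "ccf": list(c.ccf),
            } for c in clones],
        }],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return out_dir


def _probe_name(token: str) -> str:
    ab = parse_iscn(token)[0]
    if ab.region is not None and ab.region.arm in ("p", "q"):
        lo = ab.region.lo if ab.region.lo > 0 else 1.1
        band = f"{ab.region.arm}{int(lo * 10)}"
    else:
        band = "q11"
    return f"{ab.chrom}{band}"


def _write_tsv(path: Path, header: List[str], rows: List[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
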