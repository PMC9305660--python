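"""Domain types and readers for routine leukemia diagnostics.

One patient bundle integrates four evidence modalities as they arrive
from the clinic:

* somatic SNV/indel tables (gene, HGVS, VAF) from panel sequencing,
* karyotype clone descriptions in (a restricted subset of) ISCN
  notation with metaphase counts,
* interphase FISH probe counts,
* array-CGH segments with log2 ratios.

Aberrations seen by several modalities (a deletion in the karyotype, a
FISH probe on the same band, a CGH segment over the same coordinates)
are merged into a single :class:`Aberration` carrying all evidence,
matched by chromosome + region overlap.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .cytobands import BandRegion, parse_band, parse_band_interval

__all__ = [
    "Kind", "Direction", "ClinicalStatus", "Aberration", "TimePointSample",
    "VariantObservation", "KaryotypeObservation", "FishObservation",
    "CghSegment", "PatientBundle", "IscnParseError", "parse_iscn",
    "serialize_iscn", "infer_der_losses", "load_patient", "count_aberrations",
]

# Zero-width / invisible characters that leak out of publication PDFs.
_INVISIBLE = "\u200b\u200c\u200d\u2060\ufeff\u00ad"


class Kind(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"
    SV = "sv"
    CNV = "cnv"


class Direction(str, enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


class ClinicalStatus(str, enum.Enum):
    INITIAL = "initial"
    PROGRESSION = "progression"
    REMISSION = "remission"
    RELAPSE = "relapse"
    OTHER = "other"


@dataclass
class Aberration:
    """One genetic event (SNV, indel, SV or CNV)."""

    id: str
    kind: Kind
    gene: Optional[str] = None
    hgvs: Optional[str] = None
    iscn_token: Optional[str] = None
    chrom: Optional[str] = None
    region: Optional[BandRegion] = None
    cnv_direction: Optional[Direction] = None
    multiplicity: int = 1
    inferred_from: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == Kind.CNV and self.cnv_direction is None:
            raise ValueError(f"{self.id}: CNV aberration requires a direction")
        if self.kind in (Kind.SNV, Kind.INDEL) and not (self.gene and self.hgvs):
            raise ValueError(f"{self.id}: SNV/indel requires gene and HGVS")


@dataclass
class TimePointSample:
    patient: str
    label: str
    index: int
    clinical_status: ClinicalStatus = ClinicalStatus.OTHER
    therapy_marker: bool = False  # e.g. stem cell transplant before this point


@dataclass
class VariantObservation:
    aberration_id: str
    timepoint_index: int
    vaf: float
    depth: Optional[int] = None
    alt_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.depth is not None and self.alt_reads is not None:
            if abs(self.alt_reads / self.depth - self.vaf) > 1e-6:
                raise ValueError("alt_reads/depth inconsistent with vaf")


@dataclass
class KaryotypeObservation:
    timepoint_index: int
    clone_iscn: str
    metaphases_with: int
    metaphases_total: int
    aberration_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.metaphases_with <= self.metaphases_total):
            raise ValueError("metaphase counts out of range")
        if self.metaphases_total <= 0:
            raise ValueError("metaphases_total must be positive")


@dataclass
class FishObservation:
    timepoint_index: int
    probe: str
    nuclei_with: int
    nuclei_total: int
    aberration_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.nuclei_with <= self.nuclei_total):
            raise ValueError("nuclei counts out of range")
        if self.nuclei_total <= 0:
            raise ValueError("nuclei_total must be positive")


@dataclass
class CghSegment:
    timepoint_index: int
    chrom: str
    start: int
    end: int
    log2_ratio: float
    direction: Direction
    aberration_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment start must be < end")
        if self.direction == Direction.LOSS and not self.log2_ratio < 0:
            raise ValueError("loss segment requires log2_ratio < 0")
        if self.direction == Direction.GAIN and not self.log2_ratio > 0:
            raise ValueError("gain segment requires log2_ratio > 0")


@dataclass
class PatientBundle:
    patient: str
    timepoints: List[TimePointSample]
    aberrations: Dict[str, Aberration] = field(default_factory=dict)
    variant_obs: List[VariantObservation] = field(default_factory=list)
    karyotype_obs: List[KaryotypeObservation] = field(default_factory=list)
    fish_obs: List[FishObservation] = field(default_factory=list)
    cgh_segments: List[CghSegment] = field(default_factory=list)
    sex: Optional[str] = None


# --------------------------------------------------------------------------
# ISCN parsing (restricted subset)
# --------------------------------------------------------------------------

class IscnParseError(ValueError):
    """Unsupported or malformed ISCN token."""

    def __init__(self, token: str, offset: int):
        self.token = token
        self.offset = offset
        super().__init__(f"unsupported ISCN token {token!r} at offset {offset}")


_CHROM = r"(?:\d{1,2}|X|Y)"
_BANDS = r"[pq][\dpq.ter]*"

_PLOIDY_RE = re.compile(r"^\d{1,3}(?:~\d{1,3})?$")
_SEX_RE = re.compile(r"^[XY]{1,4}$")
_GAINLOSS_RE = re.compile(rf"^([+-])({_CHROM})$")
_MAR_RE = re.compile(r"^\+?(mar\d*)$")
_DER_RE = re.compile(
    rf"^\+?der\(({_CHROM})\)t\(({_CHROM}(?:;{_CHROM})+)\)"
    rf"(?:\(({_BANDS}(?:;{_BANDS})+)\))?$"
)
_T_RE = re.compile(rf"^t\(({_CHROM}(?:;{_CHROM})+)\)\(({_BANDS}(?:;{_BANDS})+)\)$")
_INS_RE = re.compile(rf"^ins\(({_CHROM}(?:;{_CHROM})*)\)\(({_BANDS}(?:;{_BANDS})*)\)$")
_INV_RE = re.compile(rf"^inv\(({_CHROM})\)\(({_BANDS})\)$")
_ADD_RE = re.compile(rf"^add\(({_CHROM})\)\(({_BANDS})\)$")
_DELDUP_RE = re.compile(rf"^(del|dup)\(({_CHROM})\)\(({_BANDS})\)$")
_ISO_RE = re.compile(rf"^i\(({_CHROM})\)\(([pq])(\d{{1,2}}(?:\.\d+)?)\)$")
_MULT_RE = re.compile(r"^(.*\S)x(\d+)$")


def _clean(text: str) -> str:
    for ch in _INVISIBLE:
        text = text.replace(ch, "")
    return "".join(text.split())


def _split_tokens(text: str) -> List[Tuple[str, int]]:
    """Split on top-level commas, returning (token, offset) pairs."""
    tokens: List[Tuple[str, int]] = []
    depth, start = 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "," and depth == 0:
            tokens.append((text[start:i], start))
            start = i + 1
    tokens.append((text[start:], start))
    return [(t, off) for t, off in tokens if t]


def _parse_token(token: str, offset: int) -> Optional[Aberration]:
    """One Aberration per token; None for ploidy prefix tokens."""
    raw = token
    uncertain = token.startswith("?")
    if uncertain:
        token = token[1:]

    multiplicity = 1
    m = _MULT_RE.match(token)
    if m and not token.startswith(("+", "-")):
        token, multiplicity = m.group(1), int(m.group(2))

    if _PLOIDY_RE.match(token) or _SEX_RE.match(token):
        return None  # modal ploidy prefix like "46,XX": consumed, discarded

    if m := _GAINLOSS_RE.match(token):
        sign, chrom = m.groups()
        direction = Direction.GAIN if sign == "+" else Direction.LOSS
        return Aberration(id=raw, kind=Kind.CNV, iscn_token=raw, chrom=chrom,
                          region=BandRegion.WHOLE, cnv_direction=direction,
                          multiplicity=multiplicity)
    if m := _MAR_RE.match(token):
        return Aberration(id=raw, kind=Kind.SV, iscn_token=raw,
                          multiplicity=multiplicity)
    if m := _DER_RE.match(token):
        chrom = m.group(1)
        return Aberration(id=raw, kind=Kind.SV, iscn_token=raw, chrom=chrom,
                          multiplicity=multiplicity)
    if m := _T_RE.match(token):
        chroms = m.group(1).split(";")
        bands = m.group(2).split(";")
        return Aberration(id=raw, kind=Kind.SV, iscn_token=raw,
                          chrom=chroms[0], region=parse_band_interval(bands[0]),
                          multiplicity=multiplicity)
    if m := _INS_RE.match(token):
        chroms = m.group(1).split(";")
        return Aberration(id=raw, kind=Kind.SV, iscn_token=raw,
                          chrom=chroms[0], multiplicity=multiplicity)
    if m := _INV_RE.match(token):
        return Aberration(id=raw, kind=Kind.SV, iscn_token=raw,
                          chrom=m.group(1),
                          region=parse_band_interval(m.group(2)),
                          multiplicity=multiplicity)
    if m := _ADD_RE.match(token):
        return Aberration(id=raw, kind=Kind.SV, iscn_token=raw,
                          chrom=m.group(1),
                          region=parse_band_interval(m.group(2)),
                          multiplicity=multiplicity)
    if m := _DELDUP_RE.match(token):
        op, chrom, bands = m.groups()
        direction = Direction.LOSS if op == "del" else Direction.GAIN
        return Aberration(id=raw, kind=Kind.CNV, iscn_token=raw, chrom=chrom,
                          region=parse_band_interval(bands),
                          cnv_direction=direction, multiplicity=multiplicity)
    if m := _ISO_RE.match(token):
        chrom, arm, _band = m.groups()
        # isochromosome: the named arm is present in extra copies
        return Aberration(id=raw, kind=Kind.CNV, iscn_token=raw, chrom=chrom,
                          region=BandRegion(arm, 0.0, math.inf),
                          cnv_direction=Direction.GAIN,
                          multiplicity=multiplicity)
    raise IscnParseError(raw, offset)


def parse_iscn(clone_string: str) -> List[Aberration]:
    """Parse a comma-separated ISCN clone description.

    Supports the subset +N, -N, del, dup, i, del/dup-style CNVs and the
    t / der(..)t(..) / ins / inv / add / mar structural tokens, each with
    an optional ``xK`` multiplicity suffix. Ploidy prefixes ("46,XX")
    are consumed and discarded; zero-width characters are stripped.
    """
    text = _clean(clone_string)
    if not text:
        return []
    out: List[Aberration] = []
    for token, offset in _split_tokens(text):
        ab = _parse_token(token, offset)
        if ab is not None:
            out.append(ab)
    return out


def serialize_iscn(aberrations: Sequence[Aberration]) -> str:
    """Inverse of :func:`parse_iscn` modulo whitespace and ploidy prefix."""
    return ",".join(a.iscn_token for a in aberrations if a.iscn_token)


_DER_LOSS_RE = re.compile(
    rf"^\+?der\(({_CHROM})\)t\(({_CHROM});({_CHROM})\)\(({_BANDS});({_BANDS})\)$"
)


def infer_der_losses(aberrations: Sequence[Aberration]) -> List[Aberration]:
    """Companion copy-number losses implied by unbalanced der(N)t(A;B).

    A derivative chromosome der(A)t(A;B)(bandA;bandB) retains the
    centromere of A but replaces the segment distal to the breakpoint on
    A with material from B: the region bandA->telomere of A is lost.
    Only two-way derivative translocations with explicit breakpoints are
    handled; everything else is left untouched.
    """
    losses: List[Aberration] = []
    for ab in aberrations:
        if ab.kind != Kind.SV or not ab.iscn_token:
            continue
        m = _DER_LOSS_RE.match(_clean(ab.iscn_token))
        if not m:
            continue
        der_chrom, c1, c2, b1, b2 = m.groups()
        partners = {c1: b1, c2: b2}
        if der_chrom not in partners or c1 == c2:
            continue
        breakpoint = parse_band(partners[der_chrom])
        region = BandRegion(breakpoint.arm, breakpoint.lo, math.inf)
        losses.append(Aberration(
            id=f"{ab.id}::loss", kind=Kind.CNV, chrom=der_chrom,
            region=region, cnv_direction=Direction.LOSS,
            inferred_from=ab.id))
    return losses


# --------------------------------------------------------------------------
# Patient loading / evidence merging
# --------------------------------------------------------------------------

_PROBE_RE = re.compile(rf"({_CHROM})([pq]\d{{1,2}}(?:\.\d+)?)")


def _variant_kind(hgvs_c: str) -> Kind:
    return Kind.INDEL if re.search(r"del|dup|ins|_", hgvs_c) else Kind.SNV


def _norm_token(token: str) -> str:
    return _clean(token).lstrip("?")


def _find_region_match(aberrations: Dict[str, Aberration], chrom: str,
                       region: BandRegion, kinds: Tuple[Kind, ...]
                       ) -> Optional[Aberration]:
    for ab in aberrations.values():
        if ab.kind not in kinds or ab.chrom != chrom or ab.region is None:
            continue
        if ab.region.overlaps(region):
            return ab
    return None


def load_patient(path) -> PatientBundle:
    """Load a patient directory into a cross-referenced bundle.

    The directory must contain ``config.yaml`` (patient id, ordered time
    points) and ``karyotype.tsv``/``variants.tsv``; ``fish.tsv`` and
    ``cgh.tsv`` are optional. All fraction-like file columns are percent;
    the bundle holds fractions.
    """
    path = Path(path)
    with open(path / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)

    patient = str(cfg["patient"])
    timepoints = []
    for i, tp in enumerate(cfg["timepoints"]):
        timepoints.append(TimePointSample(
            patient=patient, label=tp.get("label", str(i)), index=i,
            clinical_status=ClinicalStatus(tp.get("status", "other")),
            therapy_marker=bool(tp.get("transplant_before", False))))
    n_tp = len(timepoints)
    bundle = PatientBundle(patient=patient, timepoints=timepoints,
                           sex=cfg.get("sex"))

    def check_tp(idx: int, source: str) -> int:
        idx = int(idx)
        if not 0 <= idx < n_tp:
            raise ValueError(f"{source}: unknown time point index {idx}")
        return idx

    # karyotype clones -> one merged Aberration per normalized token
    karyo_path = path / "karyotype.tsv"
    if karyo_path.exists():
        kdf = pd.read_csv(karyo_path, sep="\t", dtype=str)
        for row in kdf.itertuples(index=False):
            tp = check_tp(row.timepoint, "karyotype.tsv")
            clone = row.clone_iscn if isinstance(row.clone_iscn, str) else ""
            members = []
            for ab in parse_iscn(clone):
                key = _norm_token(ab.iscn_token)
                if key not in bundle.aberrations:
                    ab.id = key
                    ab.iscn_token = key
                    bundle.aberrations[key] = ab
                members.append(key)
            bundle.karyotype_obs.append(KaryotypeObservation(
                timepoint_index=tp, clone_iscn=clone,
                metaphases_with=int(row.metaphases_with),
                metaphases_total=int(row.metaphases_total),
                aberration_ids=tuple(members)))

    # NGS variants
    var_path = path / "variants.tsv"
    if var_path.exists():
        vdf = pd.read_csv(var_path, sep="\t", dtype=str)
        vaf_col = next(c for c in vdf.columns if c.startswith("vaf"))
        for row in vdf.itertuples(index=False):
            tp = check_tp(getattr(row, "timepoint"), "variants.tsv")
            gene = getattr(row, "gene")
            hgvs_c = getattr(row, "hgvs_c")
            key = f"{gene}:{hgvs_c}"
            if key not in bundle.aberrations:
                bundle.aberrations[key] = Aberration(
                    id=key, kind=_variant_kind(hgvs_c), gene=gene,
                    hgvs=hgvs_c)
            vaf = float(getattr(row, vaf_col)) / 100.0
            depth = getattr(row, "depth", None)
            alt = getattr(row, "alt_reads", None)
            depth = int(depth) if depth and not pd.isna(depth) else None
            alt = int(alt) if alt and not pd.isna(alt) else None
            bundle.variant_obs.append(VariantObservation(
                aberration_id=key, timepoint_index=tp, vaf=vaf,
                depth=depth, alt_reads=alt))

    # optional VCF ingestion when no TSV is present
    vcf_path = path / "variants.vcf"
    if not var_path.exists() and vcf_path.exists():
        for key, kind_gene_hgvs, obs in read_vcf_variants(vcf_path):
            if key not in bundle.aberrations:
                kind, gene, hgvs = kind_gene_hgvs
                bundle.aberrations[key] = Aberration(
                    id=key, kind=kind, gene=gene, hgvs=hgvs)
            check_tp(obs.timepoint_index, "variants.vcf")
            bundle.variant_obs.append(obs)

    # FISH: attach to an existing aberration by chrom+band overlap
    fish_path = path / "fish.tsv"
    if fish_path.exists():
        fdf = pd.read_csv(fish_path, sep="\t", dtype=str)
        for row in fdf.itertuples(index=False):
            tp = check_tp(row.timepoint, "fish.tsv")
            obs = FishObservation(
                timepoint_index=tp, probe=row.probe,
                nuclei_with=int(row.nuclei_with),
                nuclei_total=int(row.nuclei_total))
            m = _PROBE_RE.search(row.probe)
            if m:
                chrom, band = m.groups()
                match = _find_region_match(
                    bundle.aberrations, chrom, parse_band(band),
                    (Kind.CNV, Kind.SV))
                if match is not None:
                    obs.aberration_id = match.id
                else:
                    key = f"fish:{row.probe}"
                    if key not in bundle.aberrations:
                        bundle.aberrations[key] = Aberration(
                            id=key, kind=Kind.SV, chrom=chrom,
                            region=parse_band(band))
                    obs.aberration_id = key
            bundle.fish_obs.append(obs)

    # array-CGH: attach to an existing CNV by coordinate->band overlap
    cgh_path = path / "cgh.tsv"
    if cgh_path.exists():
        from .cytobands import coords_to_region
        cdf = pd.read_csv(cgh_path, sep="\t", dtype=str)
        for row in cdf.itertuples(index=False):
            tp = check_tp(row.timepoint, "cgh.tsv")
            log2 = float(row.log2_ratio)
            direction = Direction.LOSS if log2 < 0 else Direction.GAIN
            seg = CghSegment(timepoint_index=tp, chrom=str(row.chrom),
                             start=int(row.start), end=int(row.end),
                             log2_ratio=log2, direction=direction)
            region = coords_to_region(seg.chrom, seg.start, seg.end)
            match = None
            if region is not None:
                match = _find_region_match(
                    bundle.aberrations, seg.chrom, region, (Kind.CNV,))
            if match is not None:
                if match.cnv_direction != direction:
                    raise ValueError(
                        f"cgh.tsv: segment {seg.chrom}:{seg.start}-{seg.end} "
                        f"direction {direction.value} conflicts with "
                        f"{match.id} ({match.cnv_direction.value})")
                seg.aberration_id = match.id
            else:
                key = f"cgh:{seg.chrom}:{region.arm if region else '*'}"
                if key not in bundle.aberrations:
                    bundle.aberrations[key] = Aberration(
                        id=key, kind=Kind.CNV, chrom=seg.chrom,
                        region=region or BandRegion.WHOLE,
                        cnv_direction=direction)
                elif bundle.aberrations[key].cnv_direction != direction:
                    raise ValueError(
                        f"cgh.tsv: conflicting directions for {key}")
                seg.aberration_id = key
            bundle.cgh_segments.append(seg)

    return bundle


def read_vcf_variants(path):
    """Optional VCF ingestion (via pysam). One record per variant call;
    the gene symbol is read from the GENE INFO field, the transcript
    change from HGVSC, the time point from the TP INFO field (default 0).
    The VAF comes from AF when present, else from the first sample's AD.

    Yields (aberration_key, (kind, gene, hgvs), VariantObservation).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gene = rec.info.get("GENE")
            hgvs = rec.info.get("HGVSC") or \
                f"c.{rec.pos}{rec.ref}>{rec.alts[0]}"
            tp = int(rec.info.get("TP", 0))
            depth = alt = None
            if "AF" in rec.info:
                af = rec.info["AF"]
                vaf = float(af[0] if isinstance(af, tuple) else af)
            else:
                sample = rec.samples[next(iter(rec.samples))]
                ad = sample["AD"]
                depth, alt = int(sum(ad)), int(ad[1])
                vaf = alt / depth
            key = f"{gene}:{hgvs}"
            yield (key, (_variant_kind(hgvs), gene, hgvs),
                   VariantObservation(aberration_id=key, timepoint_index=tp,
                                      vaf=vaf, depth=depth, alt_reads=alt))


def count_aberrations(bundle: PatientBundle) -> int:
    """Number of distinct merged aberrations across all time points."""
    return len(bundle.aberrations)
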