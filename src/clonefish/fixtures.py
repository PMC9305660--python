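"""Packaged eight-patient myeloid-neoplasia cohort fixture.

Somatic variant VAFs, karyotype clone descriptions (including the
zero-width Unicode characters that publication tables leak) and the
clinical time courses are encoded verbatim from the published cohort
overview table. That table reports WHICH clones were seen but not the
per-clone metaphase counts (those live in a supplementary file);
the ``metaphases`` numbers here are therefore SYNTHETIC stand-ins,
chosen once to be consistent with the published narrative (e.g. the
patient-7 stemline shrinking to ~5% at progression, the patient-6
derivative-17 clone large enough that both orderings of its TP53 events
remain admissible). Patient 1's table enumerates 10 aberrations while
the running text counts 11; the fixture encodes the table.

Each patient is written as the standard bundle directory
(config.yaml, variants.tsv, karyotype.tsv) consumed by
:func:`clonefish.iomodel.load_patient`.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Dict, List

import yaml

from .iomodel import PatientBundle, load_patient

__all__ = ["PATIENT_IDS", "write_patient_fixture", "load_fixture"]

ZW = "​"  # zero-width space, as found in the published strings

# (label, status, transplant_before)
_TP = lambda label, status, tx=False: {
    "label": label, "status": status, "transplant_before": tx}

# variants: (timepoint, gene, hgvs_c, hgvs_p, vaf_percent)
# karyotype: (timepoint, clone_iscn, metaphases_with, metaphases_total)
_COHORT: Dict[str, dict] = {
    "1": {
        "diagnosis": "AML",
        "timepoints": [_TP("initial", "initial")],
        "variants": [
            (0, "ASXL1", "c.2317G>T", "p.(Glu773*)", "10.83"),
            (0, "DNMT3A", "c.2645G>A", "p.(Arg882His)", "18.69"),
            (0, "IDH1", "c.394C>T", "p.(Arg132Cys)", "13.85"),
            (0, "TP53", "c.427G>A", "p.(Val143Met)", "20.49"),
        ],
        "karyotype": [
            (0, "del(5)(q14q33)", 7, 20),
            (0, f"del(5)(q14q33),-17,{ZW}{ZW}add(18)(q22),{ZW}+mar1,"
                f"{ZW}+mar2,{ZW}+mar3", 8, 20),
        ],
    },
    "2": {
        "diagnosis": "MDS",
        "sex": "male",  # BCOR/STAG2 are X-linked; VAF 66.76% needs hemizygosity
        "timepoints": [_TP("initial", "initial")],
        "variants": [
            (0, "BCOR", "c.4639+1G>A", "", "66.76"),
            (0, "DNMT3A", "c.2645G>A", "p.(Arg882His)", "39.43"),
            (0, "KRAS", "c.34G>C", "p.(Gly12Arg)", "4.03"),
            (0, "SF3B1", "c.2098A>G", "p.(Lys700Glu)", "1.31"),
            (0, "STAG2", "c.3362_3365dup", "p.(Ser1123Hisfs*14)", "52.12"),
            (0, "U2AF1", "c.101C>T", "p.(Ser34Phe)", "31.50"),
        ],
        "karyotype": [
            (0, f"+8,{ZW}+10", 16, 20),
        ],
    },
    "3": {
        "diagnosis": "t-MN",
        "timepoints": [_TP("initial", "initial")],
        "variants": [
            (0, "NF1", "c.2033del", "p.(Pro678Arg*10)", "49.52"),
        ],
        "karyotype": [
            (0, "t(12;22)(p13;q11)", 10, 25),
            (0, f"t(12;22)(p13;q11),{ZW}t(9;20)(q11;q11)", 15, 25),
        ],
    },
    "4": {
        "diagnosis": "t-MN",
        "timepoints": [_TP("initial", "initial"),
                       _TP("progression", "progression")],
        "variants": [
            (0, "IDH2", "c.419G>A", "p.(Arg140Gln)", "46.79"),
            (0, "RUNX1", "c.420T>G", "p.(Ser140Arg)", "43.00"),
            (0, "SRSF2", "c.284C>T", "p.(Pro95Leu)", "39.78"),
            (0, "TET2", "c.1455del", "p.(Asn486Thr*11)", "47.20"),
            (0, "TET2", "c.3473del", "p.(Ala1158Glu*68)", "41.43"),
            (0, "TP53", "c.844C>T", "p.(Arg282Trp)", "90.92"),
            (1, "IDH2", "c.419G>A", "p.(Arg140Gln)", "33.28"),
            (1, "KRAS", "c.35G>C", "p.(Gly12Ala)", "1.96"),
            (1, "NRAS", "c.35G>C", "p.(Gly12Ala)", "1.70"),
            (1, "PTPN11", "c.1508G>C", "p.(Gly503Ala)", "2.80"),
            (1, "RUNX1", "c.420T>G", "p.(Ser140Arg)", "38.29"),
            (1, "SRSF2", "c.284C>T", "p.(Pro95Leu)", "40.88"),
            (1, "TET2", "c.1398_1402dup", "p.(His468Leu*20)", "5.11"),
            (1, "TET2", "c.1455del", "p.(Asn486Thr*11)", "44.10"),
            (1, "TET2", "c.3473del", "p.(Ala1158Glu*68)", "36.71"),
            (1, "TP53", "c.844C>T", "p.(Arg282Trp)", "74.41"),
        ],
        "karyotype": [
            (0, "del(5)(q14q34)", 8, 20),
            (0, f"del(5)(q14q34),+8,{ZW}i(8)(q10)x2", 10, 20),
            (1, "del(5)(q14q34)", 2, 20),
            (1, "del(5)(q14q34),+8,i(8)(q10)x2", 12, 20),
            (1, f"t(2;3)(p23;q27),{ZW}del(5)(q14q34),del(7)(q21),+8,"
                f"i(8)(q10)x2", 5, 20),
        ],
    },
    "5": {
        "diagnosis": "AML",
        "timepoints": [_TP("initial", "initial"),
                       _TP("progression", "progression")],
        "variants": [
            (0, "ASXL1", "c.2077C>T", "p.(Arg693*)", "0.68"),
            (0, "KRAS", "c.38G>A", "p.(Gly13Asp)", "0.35"),
            (0, "NRAS", "c.182A>G", "p.(Gln61Arg)", "0.50"),
            (1, "ASXL1", "c.2077C>T", "p.(Arg693*)", "7.84"),
            (1, "KRAS", "c.38G>A", "p.(Gly13Asp)", "7.59"),
            (1, "NRAS", "c.182A>G", "p.(Gln61Arg)", "5.34"),
        ],
        "karyotype": [
            (0, f"t(4;14;11)(q22;q32;q23),{ZW}{ZW}add(10)(p14)", 18, 20),
            (1, "t(4;14;11)(q22;q32;q23),add(10)(p14)", 4, 20),
            (1, f"t(4;14;11)(q22;q32;q23),{ZW}{ZW}+der(4)t(4;14;11),+8,"
                f"{ZW}+9,add(10)(p14),{ZW}+19,{ZW}+21", 16, 20),
        ],
    },
    "6": {
        "diagnosis": "MPN -> sAML",
        "timepoints": [_TP("initial", "initial"),
                       _TP("progression", "progression"),
                       _TP("progression2", "progression")],
        "variants": [
            (0, "JAK2", "c.1849G>T", "p.(Val617Phe)", "73.76"),
            (1, "JAK2", "c.1849G>T", "p.(Val617Phe)", "97.53"),
            (1, "TP53", "c.814G>A", "p.(Val272Met)", "19.56"),
            (2, "JAK2", "c.1849G>T", "p.(Val617Phe)", "98.12"),
            (2, "TP53", "c.814G>A", "p.(Val272Met)", "23.36"),
        ],
        "karyotype": [
            (1, f"{ZW}add(5)(q12),{ZW}-7,{ZW}-13,{ZW}del(14)(q12q31),"
                f"{ZW}der(17)t(13;17)(q21;p12)", 16, 20),
            (2, "add(5)(q12),-7,-13,del(14)(q12q31),"
                "der(17)t(13;17)(q21;p12)", 6, 20),
            (2, f"{ZW}add(2)(q37),add(5)(q12),{ZW}-7,{ZW}-13,"
                f"{ZW}del(14)(q12q31),{ZW}der(17)t(13;17)(q21;p12),"
                f"{ZW}del(20)(q12q13)", 9, 20),
        ],
    },
    "7": {
        "diagnosis": "sAML from atypical CML",
        "timepoints": [_TP("initial", "initial"),
                       _TP("progression", "progression"),
                       _TP("remission", "remission"),
                       _TP("relapse", "relapse", tx=True)],
        "variants": [],  # no variants detected at any time point
        "karyotype": [
            (0, f"{ZW}ins(9;12)(q34;p12p13),{ZW}+12", 18, 20),
            (1, "ins(9;12)(q34;p12p13),+12", 1, 20),
            (1, f"+X,ins(9;12)(q34; p12p13), +11,{ZW}{ZW}+12,"
                f"{ZW}{ZW}del(12)(p13),+19", 17, 20),
            (3, f"der(7)t(7;9)(q35;q21),{ZW}{ZW}{ZW}ins(9;12)(q34;p12p13),"
                f"{ZW}+12", 14, 20),
        ],
    },
    "8": {
        "diagnosis": "AML without maturation",
        "timepoints": [_TP("initial", "initial"),
                       _TP("remission", "remission", tx=True),
                       _TP("relapse", "relapse"),
                       _TP("progression", "progression"),
                       _TP("remission2", "remission")],
        "variants": [
            (0, "NRAS", "c.37G>C", "p.(Gly13Arg)", "12.69"),
            (0, "WT1", "c.1136_1142dup", "p.(Ala382Thr*5)", "23.26"),
            (2, "NRAS", "c.37G>C", "p.(Gly13Arg)", "12.78"),
            (2, "NRAS", "c.37G>T", "p.(Gly13Cys)", "5.03"),
            (2, "WT1", "c.1141_1144dup", "p.(Ala382Val*4)", "4.51"),
            (2, "WT1", "c.1136_1142dup", "p.(Ala382Thr*5)", "11.35"),
            (2, "WT1", "c.1128dup", "p.(Thr377Asp*8)", "1.48"),
            (2, "WT1", "c.1110dup", "p.(Val371Cys*14)", "3.69"),
            (3, "NRAS", "c.37G>C", "p.(Gly13Arg)", "17.38"),
            (3, "NRAS", "c.37G>T", "p.(Gly13Cys)", "4.93"),
            (3, "WT1", "c.1141_1144dup", "p.(Ala382Val*4)", "4.03"),
            (3, "WT1", "c.1136_1142dup", "p.(Ala382Thr*5)", "17.18"),
            (3, "WT1", "c.1128dup", "p.(Thr377Asp*8)", "4.76"),
            (3, "WT1", "c.1110dup", "p.(Val371Cys*14)", "4.96"),
        ],
        "karyotype": [
            (0, f"{ZW}{ZW}del(9)(q21q31)", 10, 20),
            (2, "del(9)(q21q31)", 6, 20),
            (2, f"{ZW}{ZW}{ZW}{ZW}t(1;16)(p12;q21),del(9)(q21q31)", 4, 20),
            (3, "del(9)(q21q31)", 4, 20),
            (3, f"t(1;16)(p12;q21),{ZW}{ZW}?add(9)(p12),{ZW}{ZW}"
                f"del(9)(q21q31),{ZW}{ZW}add(10)(p12),add(17)(q22)", 6, 20),
        ],
    },
}

PATIENT_IDS = tuple(sorted(_COHORT))


def write_patient_fixture(patient_id: str, out_dir) -> Path:
    """Write the fixture bundle directory for one cohort patient."""
    pid = str(patient_id)
    if pid not in _COHORT:
        raise KeyError(f"unknown fixture patient {patient_id!r}; "
                       f"have {PATIENT_IDS}")
    spec = _COHORT[pid]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cfg = {"patient": f"patient{pid}",
           "timepoints": spec["timepoints"]}
    if "sex" in spec:
        cfg["sex"] = spec["sex"]
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False, allow_unicode=True)

    with open(out_dir / "variants.tsv", "w") as fh:
        fh.write("patient\ttimepoint\tgene\thgvs_c\thgvs_p\t"
                 "vaf_percent\tdepth\talt_reads\n")
        for t, gene, hc, hp, vaf in spec["variants"]:
            fh.write(f"patient{pid}\t{t}\t{gene}\t{hc}\t{hp}\t{vaf}\t\t\n")

    with open(out_dir / "karyotype.tsv", "w") as fh:
        fh.write("patient\ttimepoint\tclone_iscn\tmetaphases_with\t"
                 "metaphases_total\n")
        for t, clone, k, n in spec["karyotype"]:
            fh.write(f"patient{pid}\t{t}\t{clone}\t{k}\t{n}\n")
    return out_dir


def load_fixture(patient_id: str) -> PatientBundle:
    """Materialize and load one cohort patient."""
    with tempfile.TemporaryDirectory() as tmp:
        return load_patient(write_patient_fixture(patient_id, tmp))


def table_karyotype_strings() -> List[str]:
    """All fixture ISCN clone strings (for parser round-trip checks)."""
    return [clone for spec in _COHORT.values()
            for (_t, clone, _k, _n) in spec["karyotype"]]
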