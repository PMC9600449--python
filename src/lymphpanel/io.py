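"""Readers and writers for the formats the pipeline touches.

Conventions at the boundary: the amplicon BED is 0-based half-open (BED
standard); variant positions are 1-based (VCF standard). Missing optional
annotations are empty cells / NA tokens, never 0 — an annotated
``n_damaging_predictions`` of 0 is meaningful and must survive a
round-trip.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .models import (
    Amplicon,
    AmpliconPanel,
    ClinicalRecord,
    CoverageMatrix,
    FilterConfig,
    VariantRecord,
)

VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
    "depth",
    "variant_class",
    "protein_change",
    "cadd_phred",
    "n_damaging_predictions",
    "mutation_type",
]

_REQUIRED_VARIANT_COLUMNS = VARIANT_COLUMNS[:9]

CLINICAL_COLUMNS = [
    "patient_id",
    "treatment",
    "response",
    "relapse_flag",
    "time_to_event_months",
    "follow_up_months",
    "os_event",
    "dss_event",
    "pfs_event",
    "death_cause",
    "myc_rearranged",
]


# ---------------------------------------------------------------- panel BED


def read_amplicon_panel(path: str | Path) -> AmpliconPanel:
    """Read a BED-like amplicon definition file.

    Columns: chrom, start, end, amplicon_id[, gene]. When the gene column
    is absent the gene is parsed from the amplicon_id prefix (text before
    the first underscore). Lines starting with '#' or 'track' are skipped.
    """
    path = Path(path)
    amplicons: list[Amplicon] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path.name} line {lineno}: expected >= 4 columns")
            chrom, start_s, end_s, amp_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path.name} line {lineno}: start {start} >= end {end}"
                )
            gene = fields[4] if len(fields) >= 5 and fields[4] else amp_id.split("_")[0]
            amplicons.append(Amplicon(amp_id, gene, chrom, start, end))
    if not amplicons:
        raise ValueError(f"{path.name}: no amplicons")
    return AmpliconPanel(amplicons)


def write_amplicon_panel(panel: AmpliconPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in panel.amplicons:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.amplicon_id}\t{a.gene}\n")


# ------------------------------------------------------------ coverage TSV


def read_coverage_matrix(path: str | Path) -> CoverageMatrix:
    """TSV with first column amplicon_id, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{Path(path).name}: empty coverage matrix")
    return CoverageMatrix(df)


def write_coverage_matrix(cov: CoverageMatrix, path: str | Path) -> None:
    out = cov.df.copy()
    out.index.name = "amplicon_id"
    out.to_csv(path, sep="\t")


# ------------------------------------------------------------ variant TSV


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "."):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(v)


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read annotated variants from TSV (default) or VCF.

    TSV requires sample_id, gene, chrom, pos, ref, alt, vaf, depth,
    variant_class; protein_change, cadd_phred, n_damaging_predictions and
    mutation_type are optional and marked missing when absent. Validation
    (VAF bounds, class codes) happens in VariantRecord and rejects bad rows.
    """
    if dialect == "vcf":
        return _read_variant_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, na_values=["NA", "."], keep_default_na=True
    )
    missing = [c for c in _REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pc = d.get("protein_change", "")
        if pc is None or (isinstance(pc, float) and math.isnan(pc)):
            pc = ""
        mt = d.get("mutation_type", "other")
        if mt is None or (isinstance(mt, float) and math.isnan(mt)):
            mt = "other"
        records.append(
            VariantRecord(
                sample_id=str(d["sample_id"]),
                gene=str(d["gene"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                vaf=float(d["vaf"]),
                depth=int(d["depth"]),
                variant_class=int(d["variant_class"]),
                protein_change=str(pc),
                cadd_phred=_opt_float(d.get("cadd_phred")),
                n_damaging_predictions=_opt_int(d.get("n_damaging_predictions")),
                mutation_type=str(mt),
            )
        )
    return records


def _read_variant_vcf(path: str | Path) -> list[VariantRecord]:
    """VCF import: AF/DP from FORMAT (per sample) or INFO; annotations from
    INFO keys GENE, CLASS, PCHANGE, CADD, NDAMAGING, MTYPE."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    records: list[VariantRecord] = []
    for v in vcf:
        gene = v.INFO.get("GENE")
        if gene is None:
            raise ValueError(f"VCF record {v.CHROM}:{v.POS} lacks INFO/GENE")
        vclass = int(v.INFO.get("CLASS"))
        pc = v.INFO.get("PCHANGE") or ""
        cadd = v.INFO.get("CADD")
        ndam = v.INFO.get("NDAMAGING")
        mtype = v.INFO.get("MTYPE") or "other"
        for alt in v.ALT:
            if samples and v.format("AF") is not None:
                per_sample = zip(
                    samples,
                    v.format("AF")[:, 0].tolist(),
                    v.format("DP")[:, 0].tolist(),
                )
            else:
                per_sample = [(samples[0] if samples else "sample", v.INFO.get("AF"), v.INFO.get("DP"))]
            for sid, af, dp in per_sample:
                if af is None or (isinstance(af, float) and math.isnan(af)) or af < 0:
                    continue
                records.append(
                    VariantRecord(
                        sample_id=sid,
                        gene=str(gene),
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        vaf=float(af),
                        depth=int(dp),
                        variant_class=vclass,
                        protein_change=str(pc),
                        cadd_phred=_opt_float(cadd),
                        n_damaging_predictions=_opt_int(ndam),
                        mutation_type=str(mtype),
                    )
                )
    return records


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vaf": v.vaf,
                "depth": v.depth,
                "variant_class": v.variant_class,
                "protein_change": v.protein_change,
                "cadd_phred": v.cadd_phred,
                "n_damaging_predictions": v.n_damaging_predictions,
                "mutation_type": v.mutation_type,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    df = variants_to_frame(variants)
    # empty string / NA for missing annotations, never 0
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ------------------------------------------------------------ clinical TSV


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA", "."])
    missing = [c for c in CLINICAL_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        myc = d.get("myc_rearranged")
        if myc is None or (isinstance(myc, float) and math.isnan(myc)):
            myc = None
        else:
            myc = bool(myc) if not isinstance(myc, str) else myc.lower() == "true"
        records.append(
            ClinicalRecord(
                patient_id=str(d["patient_id"]),
                treatment=str(d["treatment"]),
                response=str(d["response"]),
                relapse_flag=_parse_bool(d["relapse_flag"]),
                time_to_event_months=float(d["time_to_event_months"]),
                follow_up_months=float(d["follow_up_months"]),
                os_event=_parse_bool(d["os_event"]),
                dss_event=_parse_bool(d["dss_event"]),
                pfs_event=_parse_bool(d["pfs_event"]),
                death_cause=str(d["death_cause"]),
                myc_rearranged=myc,
            )
        )
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    return bool(value)


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in CLINICAL_COLUMNS}
        if d["myc_rearranged"] is None:
            d["myc_rearranged"] = "NA"
        rows.append(d)
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- config


def load_config(path: str | Path) -> FilterConfig:
    """Load filtering thresholds from a YAML file of keyed values;
    unspecified keys keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(FilterConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return FilterConfig(**data)


def save_config(config: FilterConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(config, k) for k in FilterConfig.__dataclass_fields__}, fh
        )
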