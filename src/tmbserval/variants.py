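"""Variant-level front end: classify, filter and count somatic mutations.

Each patient's called mutations are reduced to a multidimensional tumor
mutation burden (TMB) vector — by default one count per mutation class
(SNV, INS, DEL) — which is the feature vector the downstream regression
model consumes.  Filtering mirrors common somatic-calling practice: a call
must be supported either by read depth or by allele fraction, and known
common polymorphisms (high population frequency) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationClass",
    "VariantCall",
    "TMBVector",
    "MalformedAlleleError",
    "classify_variant",
    "filter_variants",
    "vectorize_tmb",
    "read_variant_table",
    "write_tmb_table",
]

_VALID_BASES = frozenset("ACGTN")

DEFAULT_CLASSES = ("SNV", "INS", "DEL")


class MutationClass(str, Enum):
    """Mutation class of a small somatic variant."""

    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    OTHER = "OTHER"


class MalformedAlleleError(ValueError):
    """Raised for empty, symbolic or non-ACGTN allele strings."""


def classify_variant(ref: str, alt: str) -> MutationClass:
    """Classify a ref/alt allele pair as SNV, INS, DEL or OTHER.

    Rules (alleles taken as given, no left-alignment):

    * SNV — both alleles single bases and different;
    * INS — alt longer than ref and ref a prefix of alt;
    * DEL — ref longer than alt and alt a prefix of ref;
    * OTHER — anything else (MNVs, complex substitutions).

    Raises
    ------
    MalformedAlleleError
        If either allele is empty or contains characters outside ACGTN.
    """
    for allele in (ref, alt):
        if not allele or not set(allele) <= _VALID_BASES:
            raise MalformedAlleleError(
                f"malformed allele {allele!r}: expected non-empty ACGTN string"
            )
    if len(ref) == 1 and len(alt) == 1:
        return MutationClass.SNV if ref != alt else MutationClass.OTHER
    if len(alt) > len(ref) and alt.startswith(ref):
        return MutationClass.INS
    if len(ref) > len(alt) and ref.startswith(alt):
        return MutationClass.DEL
    return MutationClass.OTHER


@dataclass
class VariantCall:
    """One called somatic mutation with its supporting evidence.

    ``pop_freq`` is the allele frequency in a population database (1000
    Genomes / ExAC style); ``None`` means the variant is absent from those
    databases and is treated as novel (frequency 0) by the filter.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: int = 0
    vaf: float = 0.0
    pop_freq: float | None = None
    mclass: MutationClass = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.mclass is None:
            self.mclass = classify_variant(self.ref, self.alt)
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.pop_freq is not None and not 0.0 <= self.pop_freq <= 1.0:
            raise ValueError(f"pop_freq {self.pop_freq} outside [0, 1]")
        if self.alt_reads < 0:
            raise ValueError("alt_reads must be >= 0")


def filter_variants(
    calls: Sequence[VariantCall],
    min_alt_reads: int = 4,
    min_vaf: float = 0.02,
    max_pop_freq: float = 0.01,
    require_both: bool = False,
) -> list[VariantCall]:
    """Apply the support and population-frequency filters.

    A call is kept iff it is supported — strictly more than ``min_alt_reads``
    alternate reads *or* allele fraction at least ``min_vaf`` (``require_both``
    switches the disjunction to a conjunction for sensitivity analysis) —
    and it is not a known common polymorphism (``pop_freq > max_pop_freq``).
    Order is preserved and the input list is not modified.
    """
    if min_alt_reads < 0 or min_vaf < 0 or max_pop_freq < 0:
        raise ValueError("filter thresholds must be nonnegative")
    kept = []
    for call in calls:
        reads_ok = call.alt_reads > min_alt_reads
        vaf_ok = call.vaf >= min_vaf
        supported = (reads_ok and vaf_ok) if require_both else (reads_ok or vaf_ok)
        pop = 0.0 if call.pop_freq is None else call.pop_freq
        if supported and not pop > max_pop_freq:
            kept.append(call)
    return kept


@dataclass
class TMBVector:
    """Multidimensional tumor mutation burden: one count per mutation class."""

    counts: dict[str, int]
    per_mb: dict[str, float] | None = None

    @property
    def d(self) -> int:
        return len(self.counts)

    def to_array(self, per_mb: bool = False) -> np.ndarray:
        source = self.per_mb if per_mb else self.counts
        if source is None:
            raise ValueError("per-megabase values not computed (no covered_mb)")
        return np.asarray(list(source.values()), dtype=float)


def vectorize_tmb(
    calls: Iterable[VariantCall],
    classes: Sequence[str] = DEFAULT_CLASSES,
    covered_mb: float | None = None,
) -> TMBVector:
    """Count filtered calls per mutation class into a TMB vector.

    Calls whose class is not in ``classes`` (e.g. OTHER under the default
    three-class list) are dropped; the number dropped is reported through a
    warning.  ``covered_mb`` additionally yields counts per covered megabase.
    """
    if covered_mb is not None and covered_mb <= 0:
        raise ValueError(f"covered_mb must be positive, got {covered_mb}")
    counts = {c: 0 for c in classes}
    dropped = 0
    for call in calls:
        key = call.mclass.value
        if key in counts:
            counts[key] += 1
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} call(s) outside the configured classes {tuple(classes)} "
            "were dropped",
            stacklevel=2,
        )
    per_mb = None
    if covered_mb is not None:
        per_mb = {c: n / covered_mb for c, n in counts.items()}
    return TMBVector(counts=counts, per_mb=per_mb)


# ---------------------------------------------------------------------------
# readers

_MAF_CLASS_MAP = {"SNP": "SNV", "SNV": "SNV", "INS": "INS", "DEL": "DEL"}


def read_variant_table(
    path: str | Path, format: str, pop_freq_field: str = "POP_AF"
) -> dict[str, list[VariantCall]]:
    """Read per-patient variant calls from a VCF, MAF or plain TSV file.

    Returns a mapping from patient id to that patient's calls.  For VCF the
    patient id is the sample column name and a sample owns a call when it
    carries a non-reference genotype; multi-allelic records are split into
    one call per alternate allele.  For MAF the id is Tumor_Sample_Barcode;
    for TSV an explicit ``patient_id`` column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, pop_freq_field)
    if format == "maf":
        return _read_maf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown variant-table format {format!r}")


def _read_vcf(path: Path, pop_freq_field: str) -> dict[str, list[VariantCall]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: dict[str, list[VariantCall]] = {s: [] for s in samples}
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            pop = rec.INFO.get(pop_freq_field)
            gt_types = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            try:
                depths = rec.format("AD")
            except Exception:  # AD absent from FORMAT
                depths = None
            for alt_idx, alt in enumerate(rec.ALT):
                if isinstance(pop, tuple):
                    pop_a = pop[alt_idx] if alt_idx < len(pop) else None
                else:
                    pop_a = pop
                for s_idx, sample in enumerate(samples):
                    if gt_types[s_idx] not in (1, 3):
                        continue
                    alt_reads, vaf = 0, 0.0
                    if depths is not None:
                        ad = depths[s_idx]
                        if len(ad) > alt_idx + 1:
                            alt_reads = max(int(ad[alt_idx + 1]), 0)
                            total = int(np.sum(np.maximum(ad, 0)))
                            vaf = alt_reads / total if total > 0 else 0.0
                    out[sample].append(
                        VariantCall(
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref=rec.REF,
                            alt=alt,
                            alt_reads=alt_reads,
                            vaf=vaf,
                            pop_freq=None if pop_a is None else float(pop_a),
                        )
                    )
    except MalformedAlleleError:
        raise
    except Exception as exc:  # pragma: no cover - parser-dependent
        raise ValueError(f"unparseable VCF record #{record_no} in {path}: {exc}")
    return out


def _read_maf(path: Path) -> dict[str, list[VariantCall]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {
        "Tumor_Sample_Barcode",
        "Chromosome",
        "Start_Position",
        "Reference_Allele",
        "Tumor_Seq_Allele2",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAF {path} missing columns {sorted(missing)}")
    out: dict[str, list[VariantCall]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            ref, alt = row["Reference_Allele"], row["Tumor_Seq_Allele2"]
            # MAF encodes pure indels with "-" alleles; re-anchor so the
            # prefix-rule classifier applies.
            if ref == "-":
                ref, alt = "N", "N" + alt
            elif alt == "-":
                ref, alt = "N" + ref, "N"
            mclass = None
            vt = row.get("Variant_Type")
            if vt and vt in _MAF_CLASS_MAP:
                mclass = MutationClass(_MAF_CLASS_MAP[vt])
            t_alt = int(float(row["t_alt_count"])) if row.get("t_alt_count") else 0
            t_dep = int(float(row["t_depth"])) if row.get("t_depth") else 0
            pf = row.get("ExAC_AF")
            call = VariantCall(
                chrom=str(row["Chromosome"]),
                pos=int(row["Start_Position"]),
                ref=ref,
                alt=alt,
                alt_reads=t_alt,
                vaf=t_alt / t_dep if t_dep > 0 else 0.0,
                pop_freq=float(pf) if pf not in (None, "", "nan") else None,
                mclass=mclass if mclass is not None else classify_variant(ref, alt),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"unparseable MAF record at line {line_no}: {exc}")
        out.setdefault(row["Tumor_Sample_Barcode"], []).append(call)
    return out


def _read_tsv(path: Path) -> dict[str, list[VariantCall]]:
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV {path} missing columns {sorted(missing)}")
    out: dict[str, list[VariantCall]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            pf = row.get("pop_freq")
            call = VariantCall(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                alt_reads=int(row.get("alt_reads", 0) or 0),
                vaf=float(row.get("vaf", 0.0) or 0.0),
                pop_freq=None if pf is None or pd.isna(pf) else float(pf),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable variant record at line {line_no}: {exc}")
        out.setdefault(str(row["patient_id"]), []).append(call)
    return out


def write_tmb_table(
    vectors: Mapping[str, TMBVector], path: str | Path
) -> pd.DataFrame:
    """Write per-patient TMB vectors as tidy TSV (patient_id, class, count, per_mb)."""
    rows = []
    for pid, vec in vectors.items():
        for cls, n in vec.counts.items():
            rows.append(
                {
                    "patient_id": pid,
                    "class": cls,
                    "count": n,
                    "per_mb": vec.per_mb[cls] if vec.per_mb is not None else np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=["patient_id", "class", "count", "per_mb"])
    df.to_csv(path, sep="\t", index=False)
    return df
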