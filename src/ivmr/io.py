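"""Reading, validating and writing GWAS summary-statistic tables.

The on-disk dialect is delimited text (TSV by default, CSV accepted) with
one row per variant and the canonical columns

    variant_id, chr, pos, effect_allele, other_allele, eaf, beta, se, pvalue

Positions are 1-based. Missing values are written as ``NA`` and read from
either ``NA`` or an empty field. Arbitrary input headers are supported via a
column map. The eight-SNP IL-18 / T2DM instrument table used throughout the
package ships as two TSV resources and is exposed by
:func:`load_table1_fixture`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

logger = logging.getLogger("ivmr")

CANONICAL_COLUMNS = (
    "variant_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
)
MANDATORY_COLUMNS = ("variant_id", "chr", "pos", "beta", "se", "pvalue")
MISSING_TOKENS = ("", "NA")
VALID_ALLELES = frozenset("ACGT")


class SummaryStatsError(ValueError):
    """Malformed summary-statistic input (configuration or dataset level)."""


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association record with a single trait.

    ``beta`` is the per-allele effect of the effect allele: a log odds ratio
    for binary traits, SD units for quantitative traits.
    """

    variant_id: str
    chromosome: str
    position_bp: int
    beta: float
    se: float
    pvalue: float
    effect_allele: str | None = None
    other_allele: str | None = None
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise SummaryStatsError(
                f"{self.variant_id}: se must be strictly positive, got {self.se}"
            )
        if not 0 < self.pvalue <= 1:
            raise SummaryStatsError(
                f"{self.variant_id}: pvalue must lie in (0, 1], got {self.pvalue}"
            )
        if self.position_bp < 0 or int(self.position_bp) != self.position_bp:
            raise SummaryStatsError(
                f"{self.variant_id}: position_bp must be a non-negative integer"
            )
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele is not None and allele not in VALID_ALLELES:
                raise SummaryStatsError(
                    f"{self.variant_id}: {name} must be one of A/C/G/T, got {allele!r}"
                )
        if (
            self.effect_allele is not None
            and self.other_allele is not None
            and self.effect_allele == self.other_allele
        ):
            raise SummaryStatsError(
                f"{self.variant_id}: effect_allele equals other_allele"
            )
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise SummaryStatsError(
                f"{self.variant_id}: eaf must lie in (0, 1), got {self.eaf}"
            )


@dataclass(frozen=True)
class SummaryDataset:
    """An ordered, duplicate-free collection of :class:`SnpAssociation`."""

    trait_name: str
    trait_type: str  # "quantitative" or "binary"
    records: tuple[SnpAssociation, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SummaryStatsError(
                f"trait_type must be 'quantitative' or 'binary', got {self.trait_type!r}"
            )
        seen: dict[str, int] = {}
        for rec in self.records:
            seen[rec.variant_id] = seen.get(rec.variant_id, 0) + 1
        dups = sorted(v for v, n in seen.items() if n > 1)
        if dups:
            raise SummaryStatsError(f"duplicate variant_id(s): {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records)

    def get(self, variant_id: str) -> SnpAssociation:
        for rec in self.records:
            if rec.variant_id == variant_id:
                return rec
        raise KeyError(variant_id)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "chr": r.chromosome,
                "pos": r.position_bp,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _detect_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def _parse_float(token: str, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise SummaryStatsError(f"non-numeric {what}: {token!r}") from None


def _opt(token: str) -> str | None:
    return None if token in MISSING_TOKENS else token


def parse_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "quantitative",
    provenance: str | None = None,
    delimiter: str | None = None,
) -> SummaryDataset:
    """Parse a delimited summary-statistic table into a :class:`SummaryDataset`.

    Parameters
    ----------
    column_map
        Maps canonical column names to the names used in the file header,
        e.g. ``{"variant_id": "SNP", "pvalue": "P"}``. Unmapped canonical
        names are looked up verbatim.
    delimiter
        ``"\\t"`` or ``","``; auto-detected from the header when omitted.

    Rows violating a field invariant (non-positive SE, p-value outside
    (0, 1], non-numeric beta, ...) are rejected with a logged per-row
    reason; input order of the surviving rows is preserved. A missing
    mandatory column or a duplicated variant_id raises
    :class:`SummaryStatsError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _detect_delimiter(path)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        colmap.update(column_map)

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        header = reader.fieldnames or []
        for canonical in MANDATORY_COLUMNS:
            if colmap[canonical] not in header:
                raise SummaryStatsError(
                    f"mandatory column {colmap[canonical]!r} (for {canonical}) "
                    f"missing from header of {path}"
                )
        optional_present = {
            c: colmap[c] in header
            for c in ("effect_allele", "other_allele", "eaf")
        }
        records: list[SnpAssociation] = []
        for lineno, row in enumerate(reader, start=2):
            vid = row[colmap["variant_id"]]
            try:
                eaf_tok = row[colmap["eaf"]] if optional_present["eaf"] else ""
                rec = SnpAssociation(
                    variant_id=vid,
                    chromosome=row[colmap["chr"]],
                    position_bp=int(row[colmap["pos"]]),
                    beta=_parse_float(row[colmap["beta"]], "beta"),
                    se=_parse_float(row[colmap["se"]], "se"),
                    pvalue=_parse_float(row[colmap["pvalue"]], "pvalue"),
                    effect_allele=_opt(row[colmap["effect_allele"]])
                    if optional_present["effect_allele"]
                    else None,
                    other_allele=_opt(row[colmap["other_allele"]])
                    if optional_present["other_allele"]
                    else None,
                    eaf=None if eaf_tok in MISSING_TOKENS else _parse_float(eaf_tok, "eaf"),
                )
            except (SummaryStatsError, ValueError) as exc:
                logger.warning(
                    "%s line %d (%s): row rejected: %s", path.name, lineno, vid, exc
                )
                continue
            records.append(rec)

    return SummaryDataset(
        trait_name=trait_name,
        trait_type=trait_type,
        records=tuple(records),
        provenance=provenance if provenance is not None else f"parsed from {path}",
    )


def write_summary_stats(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as canonical TSV; ``NA`` marks missing fields.

    Numeric fields use Python's shortest round-tripping representation, so
    ``parse_summary_stats(write_summary_stats(d))`` reproduces ``d``
    field-for-field.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in dataset.records:
            writer.writerow(
                [
                    r.variant_id,
                    r.chromosome,
                    r.position_bp,
                    r.effect_allele if r.effect_allele is not None else "NA",
                    r.other_allele if r.other_allele is not None else "NA",
                    repr(r.eaf) if r.eaf is not None else "NA",
                    repr(r.beta),
                    repr(r.se),
                    repr(r.pvalue),
                ]
            )


_FIXTURE_NOTE = (
    "Eight-SNP IL-18 ({}) instrument table; alleles and EAFs not printed in "
    "the source and stored as missing; datasets are pre-harmonized (outcome "
    "betas oriented to the IL-18-raising allele); rs2300702 position "
    "316411522 stored verbatim although inconsistent with its ~31.6 Mb "
    "neighbourhood; LD pruning already applied upstream."
)


def load_table1_fixture() -> tuple[SummaryDataset, SummaryDataset]:
    """Load the packaged eight-SNP exposure (IL-18) and outcome (T2DM) tables.

    The fixture is constant: repeated calls return identical contents. Both
    datasets are pre-harmonized on the IL-18-raising allele and already
    LD-pruned, so they can be fed straight to the estimators.
    """
    pkg = resources.files("ivmr.data")
    with resources.as_file(pkg / "il18_exposure.tsv") as p:
        exposure = parse_summary_stats(
            p,
            trait_name="IL-18 plasma level",
            trait_type="quantitative",
            provenance=_FIXTURE_NOTE.format("exposure"),
        )
    with resources.as_file(pkg / "t2dm_outcome.tsv") as p:
        outcome = parse_summary_stats(
            p,
            trait_name="type 2 diabetes mellitus",
            trait_type="binary",
            provenance=_FIXTURE_NOTE.format("outcome"),
        )
    return exposure, outcome
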