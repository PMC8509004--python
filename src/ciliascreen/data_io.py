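"""Readers and writers for BrainSpan-style expression data and cilia gene panels.

The expression data dialect is a CSV triplet:

* ``expression_matrix.csv`` — genes x samples, first column a numeric row
  index, no header;
* ``columns_metadata.csv`` — one row per sample with the donor, an age string
  (``"4 mos"``, ``"12 yrs"``, ``"37 pcw"``), sex and a structure acronym;
* ``rows_metadata.csv`` — one row per gene with an identifier and symbol.

Conceptional ages (``pcw``) mark prenatal samples, which this pipeline
excludes at ingestion: the screen models postnatal ages 0.33–40 years only.
Structure acronyms are mapped onto a controlled vocabulary of 16 brain region
codes via an editable table; unmapped acronyms are dropped with a warning so
that atlas variants do not abort a run.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Controlled vocabulary of the 16 brain region codes used throughout.
REGION_CODES: tuple[str, ...] = (
    "ACC", "Amy", "Cer", "DLPC", "Hipp", "ITC", "MTh", "OFC",
    "PSTC", "PPC", "PAC", "PMC", "PVC", "PSSC", "Str", "VLPC",
)

#: Long anatomical names, used for the ``structure_name`` metadata column.
REGION_NAMES: dict[str, str] = {
    "ACC": "anterior (rostral) cingulate (medial prefrontal) cortex",
    "Amy": "amygdaloid complex",
    "Cer": "cerebellar cortex",
    "DLPC": "dorsolateral prefrontal cortex",
    "Hipp": "hippocampus",
    "ITC": "inferolateral temporal cortex",
    "MTh": "mediodorsal nucleus of thalamus",
    "OFC": "orbital frontal cortex",
    "PSTC": "posterior (caudal) superior temporal cortex",
    "PPC": "posteroventral (inferior) parietal cortex",
    "PAC": "primary auditory cortex",
    "PMC": "primary motor cortex",
    "PVC": "primary visual cortex",
    "PSSC": "primary somatosensory cortex",
    "Str": "striatum",
    "VLPC": "ventrolateral prefrontal cortex",
}

#: BrainSpan structure acronyms -> region codes.  Editable: pass a custom
#: mapping to :func:`read_brainspan_triplet` to handle atlas variants.  The 16
#: codes map to themselves so that files written by this package round-trip.
BRAINSPAN_ACRONYM_MAP: dict[str, str] = {
    "MFC": "ACC", "AMY": "Amy", "CBC": "Cer", "DFC": "DLPC",
    "HIP": "Hipp", "ITC": "ITC", "MD": "MTh", "OFC": "OFC",
    "STC": "PSTC", "IPC": "PPC", "A1C": "PAC", "M1C": "PMC",
    "V1C": "PVC", "S1C": "PSSC", "STR": "Str", "VFC": "VLPC",
    **{code: code for code in REGION_CODES},
}

#: Controlled vocabulary of cilia sub-structural / functional compartments.
COMPARTMENTS: frozenset[str] = frozenset({
    "axoneme", "basal body", "transition zone", "kinesin", "dynein",
    "IFT-A", "IFT-B", "BBSome", "Golgi", "cytosol", "nucleus",
    "ciliary membrane", "GPCR", "mitochondria", "centrosome", "other",
})


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class AgeParseError(DataError):
    """An age string did not match any known pattern."""


class GeneListError(DataError):
    """A gene-panel file is malformed or internally inconsistent."""


class _PrenatalMarker:
    """Singleton marker returned by :func:`parse_age` for conceptional ages."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PRENATAL"


#: Marker for prenatal ("pcw") ages; such samples are excluded downstream.
PRENATAL = _PrenatalMarker()

_AGE_RE = re.compile(r"^\s*(\d+)\s*(pcw|mos|yrs)\s*$")


def parse_age(age_string: str):
    """Parse an age string into years, or :data:`PRENATAL` for ``pcw`` ages.

    ``"N mos"`` gives ``N/12`` years at full precision (``"4 mos"`` is
    0.3333…, displayed as 0.33); ``"N yrs"`` gives ``N`` years; ``"N pcw"``
    (post-conceptional weeks) returns :data:`PRENATAL`.

    Raises
    ------
    AgeParseError
        If the string matches none of the three patterns.
    """
    m = _AGE_RE.match(str(age_string))
    if m is None:
        raise AgeParseError(f"unrecognized age string: {age_string!r}")
    value, unit = int(m.group(1)), m.group(2)
    if unit == "pcw":
        return PRENATAL
    if unit == "mos":
        return value / 12.0
    return float(value)


def format_age(age_years: float) -> str:
    """Serialize an age in years back to the nearest ``"N mos"``/``"N yrs"``.

    Ages below 2 years are written in whole months, others in whole years;
    this is the inverse of :func:`parse_age` on the representable grid.
    """
    if not np.isfinite(age_years) or age_years <= 0:
        raise DataError(f"age must be positive and finite, got {age_years!r}")
    if age_years < 2.0:
        months = max(int(round(age_years * 12.0)), 1)
        return f"{months} mos"
    return f"{int(round(age_years))} yrs"


def snap_age(age_years: float) -> float:
    """Snap a continuous age onto the representable month/year grid."""
    return parse_age(format_age(age_years))


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative, RPKM-like expression values.

    ``data`` is a DataFrame indexed by unique gene symbols with sample
    identifiers as columns.  Values must be finite and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise DataError(f"duplicate gene symbols: {list(dupes)[:5]}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise DataError("expression values must be finite")
        if values.size and values.min() < 0:
            raise DataError("expression values must be non-negative")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class SampleRecord:
    """One postnatal brain sample: donor, age in years, region code, sex."""

    sample_id: str
    donor_id: str
    age_years: float
    region: str
    sex: str

    def __post_init__(self) -> None:
        if not (0 < self.age_years <= 40):
            raise DataError(
                f"age_years must lie in (0, 40], got {self.age_years}"
            )
        if self.region not in REGION_CODES:
            raise DataError(f"unknown region code: {self.region!r}")
        if self.sex not in ("F", "M"):
            raise DataError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with its cilia sub-structural compartment membership."""

    symbol: str
    compartments: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbol:
            raise GeneListError("empty gene symbol")
        if not self.compartments:
            object.__setattr__(self, "compartments", frozenset({"other"}))
        unknown = set(self.compartments) - COMPARTMENTS
        if unknown:
            raise GeneListError(
                f"unknown compartment(s) for {self.symbol}: {sorted(unknown)}"
            )


def as_samples_frame(samples) -> pd.DataFrame:
    """Coerce a sequence of :class:`SampleRecord` (or a frame) to a DataFrame.

    Columns: sample_id, donor_id, age_years, region, sex.
    """
    if isinstance(samples, pd.DataFrame):
        required = {"sample_id", "donor_id", "age_years", "region", "sex"}
        missing = required - set(samples.columns)
        if missing:
            raise DataError(f"samples frame missing columns: {sorted(missing)}")
        return samples.reset_index(drop=True)
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "donor_id": s.donor_id,
                "age_years": s.age_years,
                "region": s.region,
                "sex": s.sex,
            }
            for s in samples
        ]
    )


def collapse_duplicates(data: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene symbol to their per-sample arithmetic mean.

    Row order follows first occurrence.  The number of collapsed rows is
    logged for provenance.
    """
    if data.index.is_unique:
        return data
    n_before = len(data)
    out = data.groupby(level=0, sort=False).mean()
    log.warning(
        "collapsed %d duplicate gene rows into %d unique symbols",
        n_before - len(out), len(out),
    )
    return out


def read_brainspan_triplet(
    expression_csv,
    columns_metadata_csv,
    rows_metadata_csv,
    acronym_map: Mapping[str, str] | None = None,
) -> tuple[ExpressionMatrix, list[SampleRecord]]:
    """Read the CSV triplet into an expression matrix plus sample records.

    Prenatal (``pcw``) samples are dropped, age strings are parsed to years,
    structure acronyms are mapped to the 16 region codes (samples with
    unmapped acronyms are dropped with a warning), and duplicate gene symbols
    are collapsed by arithmetic mean.

    Raises
    ------
    DataError
        On dimension mismatches, empty files, or if no postnatal sample
        survives filtering.
    """
    if acronym_map is None:
        acronym_map = BRAINSPAN_ACRONYM_MAP
    cols = pd.read_csv(columns_metadata_csv)
    rows = pd.read_csv(rows_metadata_csv)
    expr = pd.read_csv(expression_csv, header=None, index_col=0)
    if expr.empty or cols.empty or rows.empty:
        raise DataError("empty input file in BrainSpan triplet")
    if expr.shape[0] != len(rows):
        raise DataError(
            f"expression has {expr.shape[0]} rows but rows_metadata "
            f"describes {len(rows)}"
        )
    if expr.shape[1] != len(cols):
        raise DataError(
            f"expression has {expr.shape[1]} sample columns but "
            f"columns_metadata describes {len(cols)}"
        )

    records: list[SampleRecord] = []
    keep_positions: list[int] = []
    n_prenatal = 0
    for pos, row in enumerate(cols.itertuples(index=False)):
        age = parse_age(row.age)
        if age is PRENATAL:
            n_prenatal += 1
            continue
        region = acronym_map.get(str(row.structure_acronym))
        if region is None:
            log.warning(
                "dropping sample with unmapped structure acronym %r",
                row.structure_acronym,
            )
            continue
        column_num = getattr(row, "column_num", pos + 1)
        sex = str(row.gender).strip().upper()[:1]
        records.append(
            SampleRecord(
                sample_id=f"S{int(column_num)}",
                donor_id=str(row.donor_id),
                age_years=age,
                region=region,
                sex=sex,
            )
        )
        keep_positions.append(pos)
    if n_prenatal:
        log.info("dropped %d prenatal (pcw) samples", n_prenatal)
    if not records:
        raise DataError("no postnatal samples with mappable regions remain")

    data = expr.iloc[:, keep_positions].copy()
    data.index = pd.Index(rows["gene_symbol"].astype(str), name="gene_symbol")
    data.columns = [r.sample_id for r in records]
    data = collapse_duplicates(data)
    return ExpressionMatrix(data), records


def write_brainspan_triplet(matrix: ExpressionMatrix, samples, out_dir) -> dict[str, Path]:
    """Write the triplet dialect; inverse of :func:`read_brainspan_triplet`.

    Ages are serialized to the nearest representable ``"N mos"``/``"N yrs"``
    string; region codes are written as the structure acronyms.  Returns the
    three file paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sf = as_samples_frame(samples)
    if list(matrix.sample_ids) != list(sf["sample_id"]):
        raise DataError("matrix columns and sample metadata differ in order")

    cols = pd.DataFrame(
        {
            "column_num": np.arange(1, len(sf) + 1),
            "donor_id": sf["donor_id"],
            "donor_name": sf["donor_id"],
            "age": [format_age(a) for a in sf["age_years"]],
            "gender": sf["sex"],
            "structure_acronym": sf["region"],
            "structure_name": [REGION_NAMES[r] for r in sf["region"]],
        }
    )
    rows = pd.DataFrame(
        {
            "row_num": np.arange(1, matrix.shape[0] + 1),
            "ensembl_gene_id": ["NA"] * matrix.shape[0],
            "gene_symbol": matrix.gene_symbols,
        }
    )
    expr = matrix.data.copy()
    expr.index = np.arange(1, len(expr) + 1)

    paths = {
        "expression": out_dir / "expression_matrix.csv",
        "columns": out_dir / "columns_metadata.csv",
        "rows": out_dir / "rows_metadata.csv",
    }
    expr.to_csv(paths["expression"], header=False)
    cols.to_csv(paths["columns"], index=False)
    rows.to_csv(paths["rows"], index=False)
    return paths


def load_gene_list(tsv_path) -> list[GeneAnnotation]:
    """Load a gene-panel TSV (columns ``symbol``, ``compartments``).

    Compartments are semicolon-separated labels from the controlled
    vocabulary; an empty field defaults to ``{other}``.  Exact duplicate rows
    are deduplicated; a symbol annotated with conflicting compartment sets is
    an error.
    """
    frame = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"symbol", "compartments"}
    if not required <= set(frame.columns):
        raise GeneListError(
            f"gene list must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    seen: dict[str, frozenset[str]] = {}
    order: list[str] = []
    for row in frame.itertuples(index=False):
        symbol = row.symbol.strip()
        if not symbol:
            raise GeneListError("gene list contains an empty symbol")
        labels = frozenset(
            c.strip() for c in row.compartments.split(";") if c.strip()
        )
        if not labels:
            labels = frozenset({"other"})
        if symbol in seen:
            if seen[symbol] != labels:
                raise GeneListError(
                    f"conflicting compartment annotations for {symbol}"
                )
            continue
        seen[symbol] = labels
        order.append(symbol)
    return [GeneAnnotation(symbol=s, compartments=seen[s]) for s in order]


def write_gene_list(annotations: Iterable[GeneAnnotation], tsv_path) -> Path:
    """Write annotations as a 2-column TSV readable by :func:`load_gene_list`."""
    tsv_path = Path(tsv_path)
    tsv_path.parent.mkdir(parents=True, exist_ok=True)
    anns = list(annotations)
    frame = pd.DataFrame(
        {
            "symbol": [a.symbol for a in anns],
            "compartments": [";".join(sorted(a.compartments)) for a in anns],
        }
    )
    frame.to_csv(tsv_path, sep="\t", index=False)
    return tsv_path


def annotations_by_symbol(
    annotations: Iterable[GeneAnnotation],
) -> dict[str, frozenset[str]]:
    """Index annotations by symbol."""
    return {a.symbol: a.compartments for a in annotations}


def packaged_gene_panel_path() -> Path:
    """Path of the synthetic 445-gene cilia panel shipped with the package."""
    return Path(__file__).parent / "data" / "cilia_gene_panel_synthetic.tsv"
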