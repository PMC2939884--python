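"""Tabular data containers and delimited-text I/O.

Four file kinds move through the pipeline, each a headered, comma-delimited,
UTF-8 text file with decimal points:

* marker map      -- ``marker,chrom,pos_mb``
* genotype matrix -- ``id,<marker1>,<marker2>,...`` with cells in
  ``{AA, AB, BB}`` or the missing token (default ``-``); allele A is the
  DA allele, allele B the PVG allele
* phenotype table -- ``id,sex,family,INC,ONS,MAX,DUR,CUM,WL``
* scan result     -- ``marker,pos_mb,lod`` plus provenance in ``#``-comment
  header lines

Positions are physical megabases (real numbers); no base-pair indexing or
half-open interval conventions appear anywhere. Parsers reject malformed
input with file/line context and never silently coerce.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPE_CODES = ("AA", "AB", "BB")
MISSING_TOKEN = "-"

#: Day the observation window closes (scoring runs day 9-35 post immunization).
OBSERVATION_WINDOW_DAYS = 35

QUANTITATIVE_TRAITS = ("ONS", "MAX", "DUR", "CUM", "WL")
ALL_TRAITS = ("INC",) + QUANTITATIVE_TRAITS

PHENOTYPE_COLUMNS = ("id", "sex", "family") + ALL_TRAITS


class FormatError(ValueError):
    """Malformed pipeline table (carries file/line context in the message)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: the coordinate backbone for scans and intervals.

    Parameters
    ----------
    markers
        Unique marker names, in map order.
    chrom
        Chromosome label per marker (a single labelled region per file set).
    pos_mb
        Physical positions in Mb, strictly increasing within a chromosome.
    pos_cm
        Optional genetic positions in cM (see :func:`derive_cm_positions`
        in :mod:`ailqtl.synthdata`).
    """

    markers: tuple[str, ...]
    chrom: tuple[str, ...]
    pos_mb: np.ndarray
    pos_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        markers = tuple(str(m) for m in self.markers)
        chrom = tuple(str(c) for c in self.chrom)
        pos = np.asarray(self.pos_mb, dtype=float)
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_mb", pos)
        if self.pos_cm is not None:
            object.__setattr__(self, "pos_cm", np.asarray(self.pos_cm, float))
        if not (len(markers) == len(chrom) == pos.size):
            raise FormatError("map fields have unequal lengths")
        if len(set(markers)) != len(markers):
            raise FormatError("duplicate marker names in map")
        if np.any(pos < 0) or not np.all(np.isfinite(pos)):
            raise FormatError("map positions must be finite and >= 0")
        for c in set(chrom):
            p = pos[np.array([ci == c for ci in chrom])]
            if np.any(np.diff(p) <= 0):
                raise FormatError(
                    f"non-monotone map positions on chromosome {c!r}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def span_mb(self) -> float:
        """Total physical span covered by the map, in Mb."""
        return float(self.pos_mb[-1] - self.pos_mb[0])

    def index_of(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in map") from None

    def to_frame(self) -> pd.DataFrame:
        d = {"marker": self.markers, "chrom": self.chrom, "pos_mb": self.pos_mb}
        if self.pos_cm is not None:
            d["pos_cm"] = self.pos_cm
        return pd.DataFrame(d)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x markers genotype calls in a three-class + missing coding."""

    table: pd.DataFrame  # index: individual id (str); columns: marker names

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate individual ids: {dups[:5]}")
        if t.columns.has_duplicates:
            raise FormatError("duplicate marker columns")
        alphabet = set(GENOTYPE_CODES) | {MISSING_TOKEN}
        vals = pd.unique(t.values.ravel())
        bad = [v for v in vals if v not in alphabet]
        if bad:
            # report first offending cell with row/column context
            for col in t.columns:
                m = ~t[col].isin(alphabet)
                if m.any():
                    rid = t.index[m.argmax()]
                    raise FormatError(
                        f"genotype token {t.loc[rid, col]!r} outside alphabet "
                        f"{sorted(alphabet)} at individual {rid!r}, marker {col!r}"
                    )

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def markers(self) -> list[str]:
        return list(self.table.columns)

    def codes(self) -> np.ndarray:
        """Numeric coding: AA=0, AB=1, BB=2, missing=-1 (int8 array)."""
        arr = self.table.to_numpy(dtype=object)
        out = np.full(arr.shape, -1, dtype=np.int8)
        for i, g in enumerate(GENOTYPE_CODES):
            out[arr == g] = i
        return out

    def require_map(self, gmap: GeneticMap) -> None:
        if list(self.table.columns) != list(gmap.markers):
            raise FormatError("genotype columns do not match the marker map")


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-individual EAE traits plus sex and family (sibship) identifiers.

    INC is 0/1 incidence; ONS the day of onset (NaN when INC=0); MAX the
    maximum clinical score on the 0-4 scale; DUR days with symptoms; CUM the
    cumulative score; WL percent weight loss. Unaffected animals carry
    DUR = CUM = 0 and undefined ONS.
    """

    table: pd.DataFrame  # index: individual id

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PHENOTYPE_COLUMNS[1:] if c not in t.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns {missing}")
        if t.index.has_duplicates:
            raise FormatError("duplicate individual ids in phenotype table")
        bad_sex = set(t["sex"]) - {"F", "M"}
        if bad_sex:
            raise FormatError(f"sex values outside {{F,M}}: {sorted(bad_sex)}")
        inc = t["INC"].to_numpy()
        if not np.isin(inc, (0, 1)).all():
            raise FormatError("INC must be 0/1")
        un = inc == 0
        if np.any(~np.isnan(t["ONS"].to_numpy(float)[un])):
            raise FormatError("ONS must be undefined (empty) when INC=0")
        for c in ("DUR", "CUM"):
            if np.any(t[c].to_numpy(float)[un] != 0):
                raise FormatError(f"{c} must be 0 when INC=0")
        if np.any(t["MAX"].to_numpy(float) < 0):
            raise FormatError("MAX must be >= 0")
        if np.any(t["DUR"].to_numpy(float) > OBSERVATION_WINDOW_DAYS):
            raise FormatError(
                f"DUR exceeds the {OBSERVATION_WINDOW_DAYS}-day observation window"
            )

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def trait(self, name: str) -> np.ndarray:
        if name not in ALL_TRAITS:
            raise KeyError(f"unknown trait {name!r}; expected one of {ALL_TRAITS}")
        return self.table[name].to_numpy(dtype=float)

    @property
    def incidence(self) -> float:
        return float(self.table["INC"].mean())


@dataclass(frozen=True)
class ScanResult:
    """Per-position LOD values with model/covariate provenance."""

    positions: np.ndarray  # Mb
    lod: np.ndarray
    trait: str
    model: str  # "haley_knott" | "binary"
    covariate: str = "none"  # e.g. "none", "sex:additive", "sex:interactive"
    n: int = 0
    markers: tuple[str, ...] | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        lod = np.asarray(self.lod, float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "lod", lod)
        if pos.size != lod.size or pos.size == 0:
            raise FormatError("scan positions/LOD size mismatch or empty scan")
        if not np.all(np.isfinite(lod)) or np.any(lod < -1e-9):
            raise FormatError("LOD values must be finite and >= 0")
        object.__setattr__(self, "lod", np.maximum(lod, 0.0))

    @property
    def max_lod(self) -> float:
        return float(self.lod.max())

    @property
    def peak_position(self) -> float:
        """Position of the maximum LOD; ties broken toward smaller position."""
        return float(self.positions[int(np.argmax(self.lod))])

    @property
    def peak_marker(self) -> str | None:
        if self.markers is None:
            return None
        return self.markers[int(np.argmax(self.lod))]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_map(path) -> GeneticMap:
    df = _read_csv(path, required=("marker", "chrom", "pos_mb"))
    try:
        return GeneticMap(
            markers=tuple(df["marker"].astype(str)),
            chrom=tuple(df["chrom"].astype(str)),
            pos_mb=df["pos_mb"].to_numpy(float),
            pos_cm=df["pos_cm"].to_numpy(float) if "pos_cm" in df else None,
        )
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    geno.table.to_csv(path, index_label="id")


def read_genotypes(path, missing_token: str = MISSING_TOKEN) -> GenotypeMatrix:
    df = _read_csv(path, required=("id",))
    df = df.astype(str).set_index("id")
    if missing_token != MISSING_TOKEN:
        df = df.replace(missing_token, MISSING_TOKEN)
    try:
        return GenotypeMatrix(df)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_phenotypes(phenos: PhenotypeTable, path) -> None:
    phenos.table.to_csv(path, index_label="id", float_format="%.6g")


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_csv(path, required=PHENOTYPE_COLUMNS)
    df = df.set_index("id")
    df.index = df.index.astype(str)
    df["sex"] = df["sex"].astype(str)
    df["family"] = df["family"].astype(str)
    for c in ALL_TRAITS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["INC"] = df["INC"].astype(int)
    try:
        return PhenotypeTable(df)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_scan(scan: ScanResult, path) -> None:
    header = (
        f"# trait={scan.trait} model={scan.model} covariate={scan.covariate}"
        f" n={scan.n}"
    )
    if scan.flags:
        header += " flags=" + ",".join(scan.flags)
    body = pd.DataFrame(
        {
            "marker": scan.markers if scan.markers is not None
            else [""] * scan.positions.size,
            "pos_mb": scan.positions,
            "lod": scan.lod,
        }
    )
    buf = io.StringIO()
    buf.write(header + "\n")
    body.to_csv(buf, index=False, float_format="%.10g")
    _write_text(path, buf.getvalue())


def read_scan(path) -> ScanResult:
    text = _read_text(path)
    lines = text.splitlines()
    meta: dict[str, str] = {}
    n_comment = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_comment += 1
        for tok in line.lstrip("# ").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    df = pd.read_csv(io.StringIO("\n".join(lines[n_comment:])))
    for col in ("pos_mb", "lod"):
        if col not in df:
            raise FormatError(f"{path}: scan file missing column {col!r}")
    markers = None
    if "marker" in df and not df["marker"].isna().all():
        markers = tuple(df["marker"].astype(str))
    return ScanResult(
        positions=df["pos_mb"].to_numpy(float),
        lod=df["lod"].to_numpy(float),
        trait=meta.get("trait", "?"),
        model=meta.get("model", "?"),
        covariate=meta.get("covariate", "none"),
        n=int(meta.get("n", 0)),
        markers=markers,
        flags=tuple(meta["flags"].split(",")) if "flags" in meta else (),
    )


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except FileNotFoundError:
        raise
    except Exception as e:  # pragma: no cover - pandas error variety
        raise FormatError(f"{path}: cannot parse delimited file ({e})") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: header missing required columns {missing}")
    return df


def _read_text(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        return fh.read()


def _write_text(path, text: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def compute_wl(weights: Iterable[float], day0_weight: float) -> float:
    """Percent weight loss: lowest weight relative to the initial weight.

    The minimum is taken over the series *including* day 0, so animals that
    only gain weight get WL = 0 rather than a negative loss.
    """
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0:
        raise ValueError("weight series is empty")
    if not np.isfinite(day0_weight) or day0_weight <= 0:
        raise ValueError("initial weight must be positive")
    lowest = min(float(np.min(w)), float(day0_weight))
    return 100.0 * (day0_weight - lowest) / day0_weight


def percent_incidence(n_affected: int, n_total: int) -> float:
    """Incidence as a percentage, rounded to whole percent as reported."""
    if n_total <= 0 or n_affected < 0 or n_affected > n_total:
        raise ValueError("need 0 <= n_affected <= n_total with n_total > 0")
    return round(100.0 * n_affected / n_total)


def validate_tables(
    gmap: GeneticMap, geno: GenotypeMatrix, phenos: PhenotypeTable
) -> list[str]:
    """Cross-file conformance report; empty list means consistent."""
    problems: list[str] = []
    try:
        geno.require_map(gmap)
    except FormatError as e:
        problems.append(str(e))
    if set(geno.ids) != set(phenos.ids):
        problems.append("genotype and phenotype individual ids differ")
    return problems
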