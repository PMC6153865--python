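"""Data model and CSV I/O for baited-lander surveys.

A survey is a set of *deployments* (a camera lander free-falls to the
seabed, records images at fixed intervals, and is recovered) and, per
deployment, a set of *species observations*. Each observation carries the
three standard indicators of local density read from the image sequence:

``n_max``
    maximum number of individuals of the species visible in a single
    image — a lower bound on local abundance;
``t_arr``
    minutes from bait touchdown to the species' first appearance in frame;
``pct_images``
    percentage of seabed images in which the species was seen.

Absence is encoded by the *absence of the row*: an observation row always
has ``n_max >= 1``. :func:`build_community_matrix` zero-fills the gaps when
assembling the deployments x taxa abundance table used by the multivariate
suite.

The package bundles the eight Ionian Sea deployments (532-5111 m) and
their 14 bait-attending taxa as CSV fixtures; see
:func:`load_study_deployments` / :func:`load_study_observations`.
Ambiguously typeset cells of the source table carry a ``provenance`` note.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "DeploymentRecord",
    "SpeciesObservation",
    "CommunityMatrix",
    "AbioticTable",
    "FISH_TAXA",
    "is_fish",
    "load_deployments",
    "write_deployments",
    "load_observations",
    "write_observations",
    "build_community_matrix",
    "first_arrival_table",
    "load_study_deployments",
    "load_study_observations",
    "study_community_matrix",
    "study_abiotic_table",
]

ORIENTATIONS = ("horizontal", "vertical")

#: Fish taxa of the bundled Ionian fixture (the remaining four taxa are
#: decapod crustaceans). Used as the default filter when extracting
#: first-fish arrival times.
FISH_TAXA = frozenset(
    {
        "hexanchus griseus",
        "etmopterus spinax",
        "centrophorus granulosus",
        "dipturus oxyrinchus",
        "nettastoma melanurum",
        "conger conger",
        "coryphaenoides mediterraneus",
        "lepidion lepidion",
        "helicolenus dactylopterus",
        "polyprion americanus",
    }
)


def _norm_taxon(name: str) -> str:
    return " ".join(name.split())


def is_fish(taxon: str) -> bool:
    """True when *taxon* is one of the fixture's fish taxa (case-insensitive)."""
    return _norm_taxon(taxon).lower() in FISH_TAXA


@dataclasses.dataclass(frozen=True)
class DeploymentRecord:
    """One lander deployment with its environmental summary.

    ``current`` (cm s-1), ``temperature`` (degC) and ``salinity`` (PSU) are
    per-deployment summaries and may be missing (``None``) — the horizontal
    shallow configuration carried fewer sensors.
    """

    id: str
    depth: float  # metres below surface, > 0
    latitude: float
    longitude: float
    date: datetime.date
    duration: float  # hours recorded on the seabed
    orientation: str = "vertical"
    current: float | None = None
    temperature: float | None = None
    salinity: float | None = None
    study: str = "this_study"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError(f"deployment {self.id!r}: depth must be > 0, got {self.depth}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"deployment {self.id!r}: latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"deployment {self.id!r}: longitude {self.longitude} outside [-180, 180]")
        if self.duration < 0:
            raise ValidationError(f"deployment {self.id!r}: duration must be >= 0")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"deployment {self.id!r}: orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if self.current is not None and self.current < 0:
            raise ValidationError(f"deployment {self.id!r}: current must be >= 0")


@dataclasses.dataclass(frozen=True)
class SpeciesObservation:
    """One species seen during one deployment (presence implies n_max >= 1)."""

    deployment_id: str
    taxon: str
    n_max: int
    t_arr: float  # minutes from bait touchdown
    pct_images: float  # percent of images, in (0, 100]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon", _norm_taxon(self.taxon))
        if self.n_max < 1:
            raise ValidationError(
                f"observation ({self.deployment_id!r}, {self.taxon!r}): n_max must be >= 1 "
                "(absence is encoded by omitting the row)"
            )
        if self.t_arr < 0:
            raise ValidationError(f"observation ({self.deployment_id!r}, {self.taxon!r}): t_arr must be >= 0")
        if not 0.0 < self.pct_images <= 100.0:
            raise ValidationError(
                f"observation ({self.deployment_id!r}, {self.taxon!r}): pct_images must lie in (0, 100]"
            )


@dataclasses.dataclass
class CommunityMatrix:
    """Deployments x taxa abundance table.

    ``data`` is a DataFrame indexed by sample (deployment) id with one
    column per taxon; a cell is zero exactly when no observation exists for
    that pair. ``transform`` records the abundance transform applied
    (``"none"`` for raw counts).
    """

    data: pd.DataFrame
    transform: str = "none"

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValidationError("community matrix has negative entries")
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise ValidationError("community matrix labels must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, sample_ids: Sequence[str]) -> "CommunityMatrix":
        return CommunityMatrix(self.data.loc[list(sample_ids)].copy(), transform=self.transform)

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, transform: str = "none") -> "CommunityMatrix":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise ParseError(f"{path}: community matrix CSV must have a 'sample_id' first column")
        df["sample_id"] = df["sample_id"].astype(str)
        df = df.set_index("sample_id")
        df.index.name = None
        return cls(df.astype(float), transform=transform)


@dataclasses.dataclass
class AbioticTable:
    """Per-sample numeric environmental variables (one row per sample)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("abiotic table has duplicate sample ids")
        non_numeric = [c for c in self.data.columns if not np.issubdtype(self.data[c].dtype, np.number)]
        if non_numeric:
            raise ValidationError(f"abiotic columns must be numeric: {non_numeric}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_deployments(cls, deployments: Iterable[DeploymentRecord]) -> "AbioticTable":
        """Depth, latitude, longitude and deployment duration per sample."""
        rows = {
            d.id: {"depth": d.depth, "latitude": d.latitude, "longitude": d.longitude, "duration": d.duration}
            for d in deployments
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    def subset(self, sample_ids: Sequence[str]) -> "AbioticTable":
        return AbioticTable(self.data.loc[list(sample_ids)].copy())

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "AbioticTable":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise ParseError(f"{path}: abiotic CSV must have a 'sample_id' column")
        df["sample_id"] = df["sample_id"].astype(str)
        df = df.set_index("sample_id")
        df.index.name = None
        return cls(df.astype(float))


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_float(text: str, row: int, column: str, *, allow_missing: bool = False) -> float | None:
    text = text.strip()
    if text == "":
        if allow_missing:
            return None
        raise ParseError(f"row {row}, column {column!r}: value is required")
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"row {row}, column {column!r}: cannot parse {text!r} as a number") from exc


DEPLOYMENT_COLUMNS = (
    "id",
    "depth_m",
    "latitude",
    "longitude",
    "date",
    "duration_h",
    "orientation",
    "current_cm_s",
    "temperature_c",
    "salinity_psu",
    "study",
)


def load_deployments(path: str | Path) -> list[DeploymentRecord]:
    """Read deployment records from a headed CSV file.

    Missing environmental cells become ``None``. Raises
    :class:`~lander.errors.ParseError` naming row and column on malformed
    numbers, and :class:`~lander.errors.ValidationError` on duplicate ids
    within a study or domain violations.
    """
    records: list[DeploymentRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in DEPLOYMENT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing deployment columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                date = datetime.date.fromisoformat(row["date"].strip())
            except ValueError as exc:
                raise ParseError(f"row {i}, column 'date': cannot parse {row['date']!r} (expect YYYY-MM-DD)") from exc
            rec = DeploymentRecord(
                id=row["id"].strip(),
                depth=_parse_float(row["depth_m"], i, "depth_m"),
                latitude=_parse_float(row["latitude"], i, "latitude"),
                longitude=_parse_float(row["longitude"], i, "longitude"),
                date=date,
                duration=_parse_float(row["duration_h"], i, "duration_h"),
                orientation=row["orientation"].strip() or "vertical",
                current=_parse_float(row["current_cm_s"], i, "current_cm_s", allow_missing=True),
                temperature=_parse_float(row["temperature_c"], i, "temperature_c", allow_missing=True),
                salinity=_parse_float(row["salinity_psu"], i, "salinity_psu", allow_missing=True),
                study=row["study"].strip() or "this_study",
            )
            key = (rec.study, rec.id)
            if key in seen:
                raise ValidationError(f"duplicate deployment id {rec.id!r} within study {rec.study!r}")
            seen.add(key)
            records.append(rec)
    return records


def write_deployments(records: Iterable[DeploymentRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DEPLOYMENT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.depth,
                    r.latitude,
                    r.longitude,
                    r.date.isoformat(),
                    r.duration,
                    r.orientation,
                    "" if r.current is None else r.current,
                    "" if r.temperature is None else r.temperature,
                    "" if r.salinity is None else r.salinity,
                    r.study,
                ]
            )


OBSERVATION_COLUMNS = ("deployment_id", "taxon", "n_max", "t_arr_min", "pct_images")


def load_observations(path: str | Path) -> list[SpeciesObservation]:
    """Read species observations from a headed CSV file.

    Enforces uniqueness of (deployment, taxon) — matched case-insensitively
    after whitespace normalisation — and rejects ``n_max = 0`` rows
    (absence must be encoded by omission).
    """
    records: list[SpeciesObservation] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in OBSERVATION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing observation columns {missing}")
        for i, row in enumerate(reader, start=2):
            n_max_f = _parse_float(row["n_max"], i, "n_max")
            if n_max_f != int(n_max_f):
                raise ParseError(f"row {i}, column 'n_max': {row['n_max']!r} is not an integer")
            rec = SpeciesObservation(
                deployment_id=row["deployment_id"].strip(),
                taxon=row["taxon"],
                n_max=int(n_max_f),
                t_arr=_parse_float(row["t_arr_min"], i, "t_arr_min"),
                pct_images=_parse_float(row["pct_images"], i, "pct_images"),
                provenance=(row.get("provenance") or "").strip(),
            )
            key = (rec.deployment_id, rec.taxon.lower())
            if key in seen:
                raise ValidationError(f"duplicate observation for deployment {rec.deployment_id!r}, taxon {rec.taxon!r}")
            seen.add(key)
            records.append(rec)
    return records


def write_observations(records: Iterable[SpeciesObservation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBSERVATION_COLUMNS + ("provenance",))
        for r in records:
            writer.writerow([r.deployment_id, r.taxon, r.n_max, r.t_arr, r.pct_images, r.provenance])


# ---------------------------------------------------------------------------
# Assembly


def build_community_matrix(
    observations: Sequence[SpeciesObservation],
    deployments: Sequence[DeploymentRecord],
) -> CommunityMatrix:
    """Assemble the zero-filled deployments x taxa n_max matrix.

    Rows are ordered by increasing depth (ties by id); columns follow the
    first appearance of each taxon in *observations*. Taxon names are
    matched case-insensitively; the first-seen spelling is kept.
    """
    by_id = {d.id: d for d in deployments}
    order = sorted(deployments, key=lambda d: (d.depth, d.id))
    sample_ids = [d.id for d in order]

    canonical: dict[str, str] = {}  # lower-case -> first-seen spelling
    taxa: list[str] = []
    cells: dict[tuple[str, str], float] = {}
    for obs in observations:
        if obs.deployment_id not in by_id:
            raise ValidationError(f"observation references unknown deployment {obs.deployment_id!r}")
        low = obs.taxon.lower()
        if low not in canonical:
            canonical[low] = obs.taxon
            taxa.append(obs.taxon)
        cells[(obs.deployment_id, canonical[low])] = float(obs.n_max)

    values = np.zeros((len(sample_ids), len(taxa)))
    for (sid, taxon), v in cells.items():
        values[sample_ids.index(sid), taxa.index(taxon)] = v
    return CommunityMatrix(pd.DataFrame(values, index=sample_ids, columns=taxa), transform="none")


def first_arrival_table(
    observations: Sequence[SpeciesObservation],
    deployments: Sequence[DeploymentRecord],
    taxon_filter: Callable[[str], bool] = is_fish,
) -> pd.DataFrame:
    """Per-deployment minimum arrival time over taxa passing *taxon_filter*.

    Deployments with no qualifying observation are omitted. Returns a
    DataFrame with columns ``deployment_id, depth_m, t_arr_min, study``
    sorted by depth — the input to the arrival-time regression.
    """
    by_id = {d.id: d for d in deployments}
    best: dict[str, float] = {}
    for obs in observations:
        if obs.deployment_id not in by_id:
            raise ValidationError(f"observation references unknown deployment {obs.deployment_id!r}")
        if not taxon_filter(obs.taxon):
            continue
        cur = best.get(obs.deployment_id)
        if cur is None or obs.t_arr < cur:
            best[obs.deployment_id] = obs.t_arr
    rows = [
        {
            "deployment_id": sid,
            "depth_m": by_id[sid].depth,
            "t_arr_min": t,
            "study": by_id[sid].study,
        }
        for sid, t in best.items()
    ]
    df = pd.DataFrame(rows, columns=["deployment_id", "depth_m", "t_arr_min", "study"])
    return df.sort_values("depth_m", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bundled fixtures (the eight Ionian deployments, Table-derived)


def _data_path(name: str):
    return resources.files("lander.data").joinpath(name)


def load_study_deployments() -> list[DeploymentRecord]:
    """The eight Ionian Sea deployments (532-5111 m) bundled with the package."""
    with resources.as_file(_data_path("deployments.csv")) as p:
        return load_deployments(p)


def load_study_observations() -> list[SpeciesObservation]:
    """The 25 bundled species observations (14 taxa) with provenance notes."""
    with resources.as_file(_data_path("observations.csv")) as p:
        return load_observations(p)


def study_community_matrix() -> CommunityMatrix:
    """The bundled 8 x 14 n_max matrix, depth-ordered and zero-filled."""
    return build_community_matrix(load_study_observations(), load_study_deployments())


def study_abiotic_table() -> AbioticTable:
    return AbioticTable.from_deployments(load_study_deployments())
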