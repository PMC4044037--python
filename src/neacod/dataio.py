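"""CSV dataset bundles: the on-disk interchange format of the pipeline.

A dataset bundle is a directory of plain CSV tables sharing one year axis:
age-structured tables (landings, winter survey indices, weight-at-age,
maturity) in long form (year, age, value), annual tables (stage indices,
temperature) as (year, value), plus ``structure.json`` describing the age
structure and schema version.  Missing observations are encoded by absent
rows, never by zeros; observed values must be strictly positive.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observation import ObservationSet
from .structures import AgeStructure, Covariates

__all__ = ["DatasetBundle", "SchemaError", "write_dataset", "load_dataset"]

SCHEMA_VERSION = "1"

_AGE_TABLES = ("landings", "winter_index", "weight", "maturity")
_YEAR_TABLES = ("egg_index", "larvae_index", "zerogroup_index", "temperature")


class SchemaError(ValueError):
    """A bundle table violates the dataset schema."""


@dataclasses.dataclass(frozen=True)
class DatasetBundle:
    """File layout of one dataset directory."""

    root: Path

    def __post_init__(self) -> None:
        object.__setattr__(self, "root", Path(self.root))

    def path(self, table: str) -> Path:
        return self.root / f"{table}.csv"

    @property
    def structure_path(self) -> Path:
        return self.root / "structure.json"

    @property
    def truth_path(self) -> Path:
        return self.root / "truth.json"


def _write_age_table(path: Path, arr: np.ndarray, structure: AgeStructure) -> None:
    rows = []
    for j, year in enumerate(structure.years):
        for a in structure.ages:
            v = arr[a - 1, j]
            if np.isfinite(v):
                rows.append((int(year), int(a), float(v)))
    pd.DataFrame(rows, columns=["year", "age", "value"]).sort_values(
        ["year", "age"]).to_csv(path, index=False)


def _write_year_table(path: Path, arr: np.ndarray, structure: AgeStructure) -> None:
    rows = [(int(y), float(v)) for y, v in zip(structure.years, arr) if np.isfinite(v)]
    pd.DataFrame(rows, columns=["year", "value"]).sort_values("year").to_csv(path, index=False)


def write_dataset(bundle: DatasetBundle | str | Path, obs: ObservationSet,
                  covariates: Covariates, truth: dict | None = None) -> DatasetBundle:
    """Write an observation set and covariates as a CSV bundle.

    All tables are sorted by year then age for diffability.  If a truth
    record from the synthetic generator is given, its parameters and latent
    trajectory are stored in ``truth.json`` for recovery scoring.
    """
    if not isinstance(bundle, DatasetBundle):
        bundle = DatasetBundle(Path(bundle))
    bundle.root.mkdir(parents=True, exist_ok=True)
    st = obs.structure
    _write_age_table(bundle.path("landings"), obs.landings, st)
    _write_age_table(bundle.path("winter_index"), obs.index_winter, st)
    _write_age_table(bundle.path("weight"), covariates.weight, st)
    _write_age_table(bundle.path("maturity"), np.where(covariates.maturity > 0,
                                                       covariates.maturity, np.nan), st)
    _write_year_table(bundle.path("egg_index"), obs.index_egg, st)
    _write_year_table(bundle.path("larvae_index"), obs.index_larv, st)
    _write_year_table(bundle.path("zerogroup_index"), obs.index_0g, st)
    rows = [(int(y), float(v)) for y, v in zip(st.years, covariates.temperature)]
    pd.DataFrame(rows, columns=["year", "value"]).to_csv(bundle.path("temperature"), index=False)
    bundle.structure_path.write_text(json.dumps({
        "schema_version": SCHEMA_VERSION,
        "first_year": st.first_year, "n_years": st.n_years, "max_age": st.max_age,
        "recruit_age": st.recruit_age, "cannibal_ages": list(st.cannibal_ages),
        "dd_ages": list(st.dd_ages)}, indent=1))
    if truth is not None:
        bundle.truth_path.write_text(json.dumps(_serialise_truth(truth), indent=1))
    return bundle


def _serialise_truth(truth: dict) -> dict:
    from .structures import ParameterSet

    p: ParameterSet = truth["params"]
    latent = truth["latent"]
    return {
        "seed": truth.get("seed"),
        "params": {**{k: v for k, v in dataclasses.asdict(p).items() if k != "obs"},
                   "obs": dataclasses.asdict(p.obs)},
        "latent": {"N": latent.N.tolist(), "SSB": latent.SSB.tolist(),
                   "eggs": latent.eggs.tolist(), "larvae": latent.larvae.tolist(),
                   "zerogroup": latent.zerogroup.tolist(), "U": latent.U.tolist(),
                   "F": latent.F.tolist(), "catch": latent.catch.tolist()},
    }


def _read_age_table(path: Path, structure: AgeStructure, *, require_positive=True,
                    max_value=None) -> np.ndarray:
    if not path.exists():
        raise SchemaError(f"missing table: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != ["year", "age", "value"]:
        raise SchemaError(f"{path.name}: expected columns year, age, value")
    arr = np.full((structure.max_age, structure.n_years), np.nan)
    dup = df.duplicated(["year", "age"])
    if dup.any():
        r = df[dup].iloc[0]
        raise SchemaError(f"{path.name}: duplicate cell year={int(r.year)} age={int(r.age)}")
    for r in df.itertuples(index=False):
        if not 1 <= r.age <= structure.max_age:
            raise SchemaError(f"{path.name}: age {r.age} outside 1..{structure.max_age}")
        j = int(r.year) - structure.first_year
        if not 0 <= j < structure.n_years:
            raise SchemaError(f"{path.name}: year {int(r.year)} outside the bundle year axis")
        if require_positive and not r.value > 0:
            raise SchemaError(f"{path.name}: non-positive value at year={int(r.year)} "
                              f"age={int(r.age)} (missing cells must be absent rows)")
        if max_value is not None and r.value > max_value:
            raise SchemaError(f"{path.name}: value {r.value} exceeds {max_value}")
        arr[int(r.age) - 1, j] = r.value
    return arr


def _read_year_table(path: Path, structure: AgeStructure, *, require_positive=True,
                     allow_any_sign=False) -> np.ndarray:
    if not path.exists():
        raise SchemaError(f"missing table: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != ["year", "value"]:
        raise SchemaError(f"{path.name}: expected columns year, value")
    if df.duplicated("year").any():
        raise SchemaError(f"{path.name}: duplicate year rows")
    arr = np.full(structure.n_years, np.nan)
    for r in df.itertuples(index=False):
        j = int(r.year) - structure.first_year
        if not 0 <= j < structure.n_years:
            raise SchemaError(f"{path.name}: year {int(r.year)} outside the bundle year axis")
        if require_positive and not allow_any_sign and not r.value > 0:
            raise SchemaError(f"{path.name}: non-positive value at year={int(r.year)}")
        arr[j] = r.value
    return arr


def load_dataset(bundle: DatasetBundle | str | Path) -> tuple[ObservationSet, Covariates, AgeStructure]:
    """Load and validate a CSV bundle; inverse of :func:`write_dataset`."""
    if not isinstance(bundle, DatasetBundle):
        bundle = DatasetBundle(Path(bundle))
    if not bundle.structure_path.exists():
        raise SchemaError(f"missing structure.json in {bundle.root}")
    meta = json.loads(bundle.structure_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {meta.get('schema_version')!r}")
    st = AgeStructure(first_year=meta["first_year"], n_years=meta["n_years"],
                      max_age=meta["max_age"], recruit_age=meta["recruit_age"],
                      cannibal_ages=tuple(meta["cannibal_ages"]),
                      dd_ages=tuple(meta["dd_ages"]))
    landings = _read_age_table(bundle.path("landings"), st)
    winter = _read_age_table(bundle.path("winter_index"), st)
    egg = _read_year_table(bundle.path("egg_index"), st)
    larv = _read_year_table(bundle.path("larvae_index"), st)
    zg = _read_year_table(bundle.path("zerogroup_index"), st)
    weight = _read_age_table(bundle.path("weight"), st)
    maturity = _read_age_table(bundle.path("maturity"), st, max_value=1.0)
    temperature = _read_year_table(bundle.path("temperature"), st, allow_any_sign=True)
    if np.any(~np.isfinite(weight)):
        raise SchemaError("weight.csv must cover every modelled age and year")
    if np.any(~np.isfinite(temperature)):
        raise SchemaError("temperature.csv must cover every modelled year")
    maturity = np.where(np.isfinite(maturity), maturity, 0.0)  # absent rows = immature
    obs = ObservationSet(st, landings, winter, egg, larv, zg)
    cov = Covariates(weight=weight, maturity=maturity, temperature=temperature)
    return obs, cov, st
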