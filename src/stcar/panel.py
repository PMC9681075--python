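"""Areal space-time panels: response construction, transforms, design matrices.

The panel is a rectangular area × year table.  The response is a yield rate
E_dt = Y_dt / Z_dt (production over harvested area); covariates are climate
variables, optionally transformed (square-root temperature, log rainfall)
before entering the linear predictor.

Canonical flat ordering
-----------------------
Every flattened D·T vector in the package (responses, fitted values, random
effects of the autoregressive family) uses **time-major** order: the block
for the first year comes first, areas ascending within a year, so record
(d, t) sits at offset ``t * D + d`` (0-based indices).  A single stated
convention prevents silent misalignment between effects and observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lattice import SpatialLattice

__all__ = [
    "SpaceTimePanel",
    "TransformSpec",
    "compute_yield_rate",
    "apply_transforms",
    "validate_panel",
    "build_design",
    "read_panel_csv",
    "write_panel_csv",
    "PANEL_COLUMNS",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("temperature", "rainfall", "humidity", "windspeed", "sunshine")
PANEL_COLUMNS = ("area", "year", "response", "exposure") + DEFAULT_COVARIATES

#: Default transform set used throughout: temperature on the square-root
#: scale, rainfall on the natural-log scale, everything else untouched.
DEFAULT_TRANSFORMS = {"temperature": "sqrt", "rainfall": "log"}


@dataclass(frozen=True)
class SpaceTimePanel:
    """Rectangular areal panel in canonical time-major order.

    Attributes
    ----------
    n_areas, n_times
        Panel dimensions D and T.
    response
        Flat response vector E_dt, length D·T, offset ``t*D + d``.
    covariates
        Mapping covariate name -> flat D·T array (same ordering).
    exposure
        Optional flat harvested-area vector Z_dt.
    area_labels, time_labels
        Human labels (district names, calendar years) aligned with indices;
        the lexicon for reproducible joins with input files.
    """

    n_areas: int
    n_times: int
    response: np.ndarray
    covariates: dict[str, np.ndarray]
    exposure: np.ndarray | None = None
    area_labels: tuple[str, ...] | None = field(default=None, compare=False)
    time_labels: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self):
        n = self.n_areas * self.n_times
        object.__setattr__(self, "response", np.asarray(self.response, float))
        if self.response.shape != (n,):
            raise ValueError(
                f"response length {self.response.shape} != D*T = {n}"
            )
        covs = {k: np.asarray(v, float) for k, v in self.covariates.items()}
        for k, v in covs.items():
            if v.shape != (n,):
                raise ValueError(f"covariate {k!r} length {v.shape} != D*T = {n}")
        object.__setattr__(self, "covariates", covs)
        if self.exposure is not None:
            exp = np.asarray(self.exposure, float)
            if exp.shape != (n,):
                raise ValueError(f"exposure length {exp.shape} != D*T = {n}")
            object.__setattr__(self, "exposure", exp)

    @property
    def n_records(self) -> int:
        return self.n_areas * self.n_times

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariates)

    def flat_index(self, d: int, t: int) -> int:
        """Offset of record (area d, time t) in any flat vector."""
        return t * self.n_areas + d

    def get_area_labels(self) -> tuple[str, ...]:
        if self.area_labels is not None:
            return self.area_labels
        return tuple(str(d) for d in range(self.n_areas))

    def get_time_labels(self) -> tuple[str, ...]:
        if self.time_labels is not None:
            return self.time_labels
        return tuple(str(t + 1) for t in range(self.n_times))

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame in canonical record order."""
        D, T = self.n_areas, self.n_times
        alab, tlab = self.get_area_labels(), self.get_time_labels()
        data = {
            "area": [alab[d] for t in range(T) for d in range(D)],
            "year": [tlab[t] for t in range(T) for d in range(D)],
            "response": self.response,
        }
        if self.exposure is not None:
            data["exposure"] = self.exposure
        for k, v in self.covariates.items():
            data[k] = v
        return pd.DataFrame(data)


@dataclass(frozen=True)
class TransformSpec:
    """Per-covariate transform tags: ``identity``, ``sqrt`` or ``log``.

    ``sqrt`` requires non-negative inputs; ``log`` (natural log) strictly
    positive ones.  Unlisted covariates are left untouched.
    """

    transforms: dict[str, str]

    _ALLOWED = ("identity", "sqrt", "log")

    def __post_init__(self):
        for name, tag in self.transforms.items():
            if tag not in self._ALLOWED:
                raise ValueError(
                    f"unknown transform {tag!r} for {name!r}; "
                    f"allowed: {self._ALLOWED}"
                )

    @classmethod
    def default(cls) -> "TransformSpec":
        return cls(dict(DEFAULT_TRANSFORMS))


def compute_yield_rate(production, area):
    """Yield rate E = Y / Z: production (metric tons) over harvested area (acres).

    Works elementwise on arrays.  Zero or negative area is an invalid
    exposure; negative production an invalid value.
    """
    production = np.asarray(production, float)
    area = np.asarray(area, float)
    if np.any(area <= 0):
        raise ValueError("invalid exposure: harvested area must be > 0")
    if np.any(production < 0):
        raise ValueError("invalid value: production must be >= 0")
    out = production / area
    return float(out) if out.ndim == 0 else out


def apply_transforms(panel: SpaceTimePanel, spec: TransformSpec) -> SpaceTimePanel:
    """Return a panel with transformed covariate columns.

    Untouched columns are preserved; domain violations raise a ``ValueError``
    naming the offending record.
    """
    new_covs = {}
    D = panel.n_areas
    alab, tlab = panel.get_area_labels(), panel.get_time_labels()
    for name, vals in panel.covariates.items():
        tag = spec.transforms.get(name, "identity")
        if tag == "identity":
            new_covs[name] = vals
            continue
        if tag == "sqrt":
            bad = np.flatnonzero(vals < 0)
            op = np.sqrt
        else:  # log
            bad = np.flatnonzero(vals <= 0)
            op = np.log
        if bad.size:
            i = int(bad[0])
            d, t = i % D, i // D
            raise ValueError(
                f"{tag} domain error for covariate {name!r} at record "
                f"(area={alab[d]}, year={tlab[t]}): value {vals[i]}"
            )
        new_covs[name] = op(vals)
    return replace(panel, covariates=new_covs)


def validate_panel(panel: SpaceTimePanel, lattice: SpatialLattice | None = None):
    """Structural validation; returns a list of violation strings (empty = valid).

    Checks rectangular completeness (the constructor enforces D·T records, so
    this reports NaN holes), index/label consistency with the lattice, and
    covariate completeness.
    """
    violations: list[str] = []
    D, T = panel.n_areas, panel.n_times
    alab, tlab = panel.get_area_labels(), panel.get_time_labels()

    miss = np.flatnonzero(~np.isfinite(panel.response))
    for i in miss:
        d, t = int(i) % D, int(i) // D
        violations.append(
            f"missing/non-finite response at (area={alab[d]}, year={tlab[t]})"
        )
    for name, vals in panel.covariates.items():
        bad = np.flatnonzero(~np.isfinite(vals))
        for i in bad:
            d, t = int(i) % D, int(i) // D
            violations.append(
                f"missing/non-finite covariate {name!r} at "
                f"(area={alab[d]}, year={tlab[t]})"
            )
    if lattice is not None:
        if lattice.n_areas != D:
            violations.append(
                f"lattice has {lattice.n_areas} areas but panel has {D}"
            )
        elif lattice.labels is not None and panel.area_labels is not None:
            if tuple(lattice.labels) != tuple(panel.area_labels):
                violations.append("lattice and panel area labels disagree")
    return violations


def build_design(panel: SpaceTimePanel, covariate_names=None):
    """Design matrix and response vector in canonical time-major row order.

    The first column is the intercept (all ones); the remaining columns are
    the named covariates in the given order.  An empty name list yields the
    intercept-only design.

    Returns
    -------
    X : ndarray of shape (D*T, 1 + len(covariate_names))
    y : ndarray of shape (D*T,)
    names : tuple of column names, starting with ``"Intercept"``
    """
    if covariate_names is None:
        covariate_names = panel.covariate_names
    cols = [np.ones(panel.n_records)]
    for name in covariate_names:
        if name not in panel.covariates:
            raise KeyError(
                f"unknown covariate {name!r}; panel has {panel.covariate_names}"
            )
        cols.append(panel.covariates[name])
    X = np.column_stack(cols)
    return X, panel.response.copy(), ("Intercept", *covariate_names)


def _panel_from_frame(df: pd.DataFrame) -> SpaceTimePanel:
    required = {"area", "year", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    area_labels = tuple(sorted(df["area"].astype(str).unique()))
    # years sort numerically when possible, else lexicographically
    years = df["year"].unique()
    try:
        time_labels = tuple(str(y) for y in sorted(years, key=float))
    except (TypeError, ValueError):
        time_labels = tuple(sorted(str(y) for y in years))
    D, T = len(area_labels), len(time_labels)
    aidx = {a: i for i, a in enumerate(area_labels)}
    tidx = {y: i for i, y in enumerate(time_labels)}

    n = D * T
    flat = df["year"].astype(str).map(tidx).to_numpy() * D + (
        df["area"].astype(str).map(aidx).to_numpy()
    )
    if len(df) != n or len(np.unique(flat)) != len(df):
        raise ValueError(
            f"panel is not a complete rectangle: {len(df)} rows for "
            f"{D} areas x {T} years (expected {n} unique (area, year) cells)"
        )
    cov_names = [
        c for c in df.columns if c not in ("area", "year", "response", "exposure")
    ]
    resp = np.full(n, np.nan)
    resp[flat] = df["response"].to_numpy(float)
    exposure = None
    if "exposure" in df.columns and df["exposure"].notna().all():
        exposure = np.full(n, np.nan)
        exposure[flat] = df["exposure"].to_numpy(float)
    covs = {}
    for c in cov_names:
        v = np.full(n, np.nan)
        v[flat] = df[c].to_numpy(float)
        covs[c] = v
    return SpaceTimePanel(
        n_areas=D,
        n_times=T,
        response=resp,
        covariates=covs,
        exposure=exposure,
        area_labels=area_labels,
        time_labels=time_labels,
    )


def read_panel_csv(path) -> SpaceTimePanel:
    """Read the standard panel CSV.

    Header ``area,year,response,exposure,<covariates...>`` (exposure column
    optional); UTF-8, "." decimal.  Rows may arrive in any order — records
    are canonically sorted, so permuting the file never changes the design.
    If ``response`` is absent but ``production`` and ``exposure`` are
    present, the response is built as the yield rate production/exposure.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "response" not in df.columns and {"production", "exposure"} <= set(df.columns):
        df = df.copy()
        df["response"] = compute_yield_rate(
            df["production"].to_numpy(float), df["exposure"].to_numpy(float)
        )
        df = df.drop(columns=["production"])
    return _panel_from_frame(df)


def write_panel_csv(panel: SpaceTimePanel, path) -> None:
    """Write the standard panel CSV in canonical record order."""
    panel.to_frame().to_csv(path, index=False, float_format="%.17g")
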