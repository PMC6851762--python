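"""Sparse design matrix with B-spline bases and hierarchy interactions.

Each of the six covariates (humidity, air temperature, same-month
precipitation, prior-12-month precipitation, wind speed, log housing
density) gets a univariate B-spline basis with ``df`` columns (default 5,
whose span includes the constant function). The global basis block is then
interacted with the region hierarchy: for every L1, L2 and L3 unit the
global basis columns are copied and masked to rows belonging to that unit,
so a region's effective coefficient vector decomposes additively into
global + L1 + L2 + L3 adjustments. Indicator columns adjust the global
intercept per region unit.

Column count: with B univariate basis vectors and R = #L1 + #L2 + #L3
region units, p = B * (1 + R) + R. Each row has at most 4B + 3 nonzeros
(its global, L1, L2 and L3 basis copies plus three intercept indicators),
so the matrix is overwhelmingly sparse for realistic hierarchies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import BSpline

from fire_extremes.hierarchy import EcoregionHierarchy

logger = logging.getLogger(__name__)

LEVELS = ("global", "L1", "L2", "L3")


@dataclass(frozen=True)
class SplineSpec:
    """A fitted univariate B-spline basis specification.

    Boundary knots sit at the training minimum and maximum; the
    ``n_interior = df - degree - 1`` interior knots sit at equally spaced
    training quantiles. ``log_transform`` applies log() before basis
    evaluation (used for housing density).
    """

    covariate: str
    df: int
    degree: int
    boundary: tuple[float, float]
    interior_knots: tuple[float, ...]
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.df < 2:
            raise ValueError("spline df must be >= 2")
        lo, hi = self.boundary
        knots = self.interior_knots
        if any(not (lo < k < hi) for k in knots):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if any(b >= a for a, b in zip(knots[1:], knots[:-1])):
            raise ValueError("interior knots must be strictly increasing")

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        k = self.degree
        return np.array([lo] * (k + 1) + list(self.interior_knots) + [hi] * (k + 1))


def make_spline_spec(
    values: np.ndarray,
    df: int = 5,
    covariate: str = "x",
    log_transform: bool = False,
) -> SplineSpec:
    """Fit a spline specification to training values.

    Uses clamped cubic B-splines (degree lowered for very small df so the
    basis dimension equals df). Interior knots are placed at equally
    spaced quantiles of the training values; duplicated quantiles are an
    error (too little spread).
    """
    values = np.asarray(values, dtype=float)
    if log_transform:
        if np.any(values <= 0):
            raise ValueError(f"{covariate}: log transform needs positive values")
        values = np.log(values)
    distinct = np.unique(values)
    if distinct.size < df:
        raise ValueError(
            f"{covariate}: need >= {df} distinct training values, got {distinct.size}"
        )
    degree = min(3, df - 1)
    n_interior = df - degree - 1
    lo, hi = float(distinct.min()), float(distinct.max())
    if n_interior > 0:
        qs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(values, qs)
        if np.unique(interior).size < n_interior or np.any((interior <= lo) | (interior >= hi)):
            raise ValueError(f"{covariate}: interior knot quantiles are degenerate")
    else:
        interior = np.array([])
    return SplineSpec(covariate, df, degree, (lo, hi), tuple(float(k) for k in interior), log_transform)


def evaluate_basis(spec: SplineSpec, x) -> np.ndarray:
    """Evaluate the df basis functions at x (rows sum to one).

    Values outside the boundary knots are clamped to the boundary before
    evaluation (bounded extrapolation), with a logged warning.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{spec.covariate}: non-finite input to basis evaluation")
    if spec.log_transform:
        if np.any(x <= 0):
            raise ValueError(f"{spec.covariate}: log transform needs positive values")
        x = np.log(x)
    lo, hi = spec.boundary
    n_out = int(np.sum((x < lo) | (x > hi)))
    if n_out:
        logger.warning(
            "%s: %d value(s) outside the training range [%.4g, %.4g]; clamping",
            spec.covariate, n_out, lo, hi,
        )
        x = np.clip(x, lo, hi)
    out = BSpline.design_matrix(x, spec.knot_vector, spec.degree).toarray()
    assert out.shape[1] == spec.df
    return out


class DesignMatrix:
    """Sparse design matrix plus per-column metadata.

    ``meta`` has one row per column with fields: kind ('basis' or
    'intercept_adjustment'), covariate (or None), basis_index (or -1),
    level ('global', 'L1', 'L2', 'L3'), region (unit id, or -1 for
    global columns).
    """

    def __init__(self, X: sparse.spmatrix, meta: pd.DataFrame):
        if X.shape[1] != len(meta):
            raise ValueError("metadata must cover every column exactly once")
        self.X = X.tocsr()
        self.meta = meta.reset_index(drop=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def toarray(self) -> np.ndarray:
        return self.X.toarray()

    def columns_for(
        self,
        kind: str | None = None,
        covariate: str | None = None,
        level: str | None = None,
        region: int | None = None,
    ) -> np.ndarray:
        m = np.ones(len(self.meta), dtype=bool)
        if kind is not None:
            m &= (self.meta["kind"] == kind).to_numpy()
        if covariate is not None:
            m &= (self.meta["covariate"] == covariate).to_numpy()
        if level is not None:
            m &= (self.meta["level"] == level).to_numpy()
        if region is not None:
            m &= (self.meta["region"] == region).to_numpy()
        return np.flatnonzero(m)

    # -- serialization ---------------------------------------------------

    def to_files(self, triples_path, meta_path) -> None:
        coo = self.X.tocoo()
        pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
            triples_path, index=False
        )
        payload = {
            "shape": list(self.X.shape),
            "columns": self.meta.to_dict(orient="records"),
        }
        with open(meta_path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_files(cls, triples_path, meta_path) -> "DesignMatrix":
        with open(meta_path) as fh:
            payload = json.load(fh)
        t = pd.read_csv(triples_path)
        X = sparse.coo_matrix(
            (t["value"], (t["row"], t["col"])), shape=tuple(payload["shape"])
        )
        return cls(X, pd.DataFrame(payload["columns"]))


def fit_spline_specs(
    train: pd.DataFrame,
    covariates: tuple[str, ...],
    df: int = 5,
    log_transform: tuple[str, ...] = ("housing_density",),
) -> dict[str, SplineSpec]:
    """Fit one SplineSpec per covariate from training rows only."""
    return {
        c: make_spline_spec(
            train[c].to_numpy(), df=df, covariate=c, log_transform=c in log_transform
        )
        for c in covariates
    }


def build_design_matrix(
    data: pd.DataFrame,
    hierarchy: EcoregionHierarchy,
    specs: dict[str, SplineSpec],
) -> DesignMatrix:
    """Assemble the sparse design matrix for panel cells or event rows.

    ``data`` needs a ``region`` column (L3 id) plus one column per fitted
    spec. Column order: the global basis block, then L1, L2 and L3
    interaction blocks (each sorted by covariate then region id), then the
    intercept-adjustment indicators (L1, then L2, then L3, by region id).
    """
    unknown = set(data["region"]) - set(hierarchy.l3_ids)
    if unknown:
        raise ValueError(f"rows reference regions absent from hierarchy: {sorted(unknown)}")

    covs = list(specs)
    n = len(data)
    global_blocks = [evaluate_basis(specs[c], data[c].to_numpy()) for c in covs]
    G = np.hstack(global_blocks)  # n x B
    B = G.shape[1]

    l3 = data["region"].to_numpy()
    l2 = np.array([hierarchy.parent_l2[r] for r in l3])
    l1 = np.array([hierarchy.l1_of_l3(r) for r in l3])
    level_units = {
        "L1": (hierarchy.l1_ids, l1),
        "L2": (hierarchy.l2_ids, l2),
        "L3": (hierarchy.l3_ids, l3),
    }

    blocks: list[sparse.spmatrix] = [sparse.csr_matrix(G)]
    meta_rows: list[dict] = [
        {"kind": "basis", "covariate": c, "basis_index": b, "level": "global", "region": -1}
        for c in covs
        for b in range(specs[c].df)
    ]

    for level in ("L1", "L2", "L3"):
        units, row_unit = level_units[level]
        for ci, c in enumerate(covs):
            df_c = specs[c].df
            offset = sum(specs[covs[k]].df for k in range(ci))
            sub = G[:, offset : offset + df_c]
            for u in units:
                mask = (row_unit == u).astype(float)[:, None]
                blocks.append(sparse.csr_matrix(sub * mask))
                meta_rows.extend(
                    {"kind": "basis", "covariate": c, "basis_index": b, "level": level, "region": u}
                    for b in range(df_c)
                )

    for level in ("L1", "L2", "L3"):
        units, row_unit = level_units[level]
        for u in units:
            col = (row_unit == u).astype(float)[:, None]
            blocks.append(sparse.csr_matrix(col))
            meta_rows.append(
                {
                    "kind": "intercept_adjustment",
                    "covariate": None,
                    "basis_index": -1,
                    "level": level,
                    "region": u,
                }
            )

    X = sparse.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows)
    R = hierarchy.n_l1 + hierarchy.n_l2 + hierarchy.n_l3
    assert X.shape == (n, B * (1 + R) + R)
    return DesignMatrix(X, meta)


def coefficient_for_region(
    beta: np.ndarray,
    design: DesignMatrix,
    covariate: str,
    l3_region: int,
    hierarchy: EcoregionHierarchy,
) -> np.ndarray:
    """Effective basis coefficients (global + L1 + L2 + L3) for one region.

    This is the quantity behind partial-effect curves: its dot product
    with a basis row gives that covariate's contribution to the linear
    predictor for a cell in the region.
    """
    if l3_region not in hierarchy.parent_l2:
        raise ValueError(f"unknown region {l3_region}")
    if covariate not in set(design.meta["covariate"].dropna()):
        raise ValueError(f"unknown covariate {covariate!r}")
    beta = np.asarray(beta, dtype=float)
    units = {
        "global": -1,
        "L1": hierarchy.l1_of_l3(l3_region),
        "L2": hierarchy.parent_l2[l3_region],
        "L3": l3_region,
    }
    total = None
    for level, unit in units.items():
        idx = design.columns_for(kind="basis", covariate=covariate, level=level, region=unit)
        part = beta[idx]
        total = part if total is None else total + part
    return total
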