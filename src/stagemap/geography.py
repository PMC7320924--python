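"""Small-area geography: adjacency, centroids, income and deprivation quintiles.

Real small-area systems (such as Sweden's Demographic Statistics Areas,
~600-2,600 residents each) provide polygons, an adjacency structure and
area-level median household income. For simulation we emulate them with a
rectangular lattice under rook adjacency: spatial smoothing only consumes
the adjacency graph, so the lattice is the simplest connected stand-in.

Deprivation is coded as income quintiles of *areas* (Q1 poorest ... Q5
wealthiest), computed separately for each geographic scope (the whole
region, or a named urban subarea), mirroring how local and regional
analyses each use their own quintile classification.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from ._schema import QUINTILES

__all__ = ["Geography", "generate_geography", "assign_quintiles"]


class Geography:
    """Areas with adjacency, centroids, income and quintile labels.

    Parameters
    ----------
    areas : pandas.DataFrame
        Indexed by ``area_id`` with at least columns ``x``, ``y`` (planar
        centroid coordinates) and ``median_income``. A ``quintile`` column
        (region-wide scope) is added on construction if incomes are present.
    adjacency : iterable of (area_id, area_id)
        Undirected edges; symmetry is enforced, self-loops rejected.
    polygons : mapping area_id -> shapely Polygon, optional
    subareas : mapping name -> list of area_id, optional
        Named urban subareas; each gets its own quintile classification via
        :meth:`quintiles`.
    """

    def __init__(self, areas: pd.DataFrame, adjacency: Iterable[tuple[str, str]],
                 polygons: Mapping[str, Polygon] | None = None,
                 subareas: Mapping[str, list[str]] | None = None):
        self.areas = areas.copy()
        self.areas.index = self.areas.index.astype(str)
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.areas.index)
        for a, b in adjacency:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-adjacency for area {a!r}")
            if a not in self.areas.index or b not in self.areas.index:
                raise ValueError(f"adjacency edge ({a}, {b}) references unknown area")
            self.graph.add_edge(a, b)
        self.polygons = dict(polygons) if polygons else {}
        self.subareas = {k: [str(a) for a in v] for k, v in (subareas or {}).items()}
        for name, members in self.subareas.items():
            missing = set(members) - set(self.areas.index)
            if missing:
                raise ValueError(f"subarea {name!r} references unknown areas {sorted(missing)}")
        if ("median_income" in self.areas and "quintile" not in self.areas
                and len(self.areas) >= 5):
            self.areas["quintile"] = self.quintiles()

    # -- basic accessors ---------------------------------------------------
    @property
    def area_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def neighbors(self, area_id: str) -> set[str]:
        return set(self.graph.neighbors(area_id))

    def centroids(self) -> pd.DataFrame:
        return self.areas[["x", "y"]]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def quintiles(self, scope: str | None = None) -> pd.Series:
        """Quintile labels for a scope (``None`` = whole region)."""
        ids = self.area_ids if scope is None else self.subareas[scope]
        return assign_quintiles(self.areas.loc[ids, "median_income"])

    # -- serialisation -----------------------------------------------------
    def adjacency_table(self) -> pd.DataFrame:
        rows = [(a, b) for a, b in self.graph.edges]
        rows += [(b, a) for a, b in self.graph.edges]
        return (pd.DataFrame(rows, columns=["area_id", "neighbor_id"])
                .sort_values(["area_id", "neighbor_id"]).reset_index(drop=True))

    def to_geojson(self) -> dict:
        feats = []
        for aid, row in self.areas.iterrows():
            geom = self.polygons.get(aid)
            props = {"area_id": aid,
                     "median_income": float(row["median_income"]),
                     "quintile": row.get("quintile")}
            for name, members in self.subareas.items():
                props[f"subarea_{name}"] = aid in members
            feats.append({
                "type": "Feature",
                "geometry": mapping(geom) if geom is not None else
                {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": props,
            })
        return {"type": "FeatureCollection", "features": feats}

    def write(self, geojson_path, adjacency_path) -> None:
        with open(geojson_path, "w") as fh:
            json.dump(self.to_geojson(), fh)
        self.adjacency_table().to_csv(adjacency_path, index=False)

    @classmethod
    def read(cls, geojson_path, adjacency_path) -> "Geography":
        with open(geojson_path) as fh:
            gj = json.load(fh)
        recs: list[dict] = []
        polys: dict[str, Polygon] = {}
        sub: dict[str, list[str]] = {}
        for feat in gj["features"]:
            props = feat["properties"]
            aid = str(props["area_id"])
            geom = shape(feat["geometry"])
            if geom.geom_type == "Point":
                x, y = geom.x, geom.y
            else:
                polys[aid] = geom
                c = geom.centroid
                x, y = c.x, c.y
            recs.append({"area_id": aid, "x": x, "y": y,
                         "median_income": props["median_income"],
                         "quintile": props.get("quintile")})
            for key, val in props.items():
                if key.startswith("subarea_") and val:
                    sub.setdefault(key[len("subarea_"):], []).append(aid)
        areas = pd.DataFrame(recs).set_index("area_id")
        adj = pd.read_csv(adjacency_path, dtype=str)
        edges = list(zip(adj["area_id"], adj["neighbor_id"]))
        return cls(areas, edges, polygons=polys, subareas=sub)


def assign_quintiles(incomes: pd.Series, scope: Iterable[str] | None = None) -> pd.Series:
    """Label each area Q1 (poorest fifth) ... Q5 (wealthiest fifth).

    Quintiles are fifths of *areas* ranked by income, not population
    weighted. Group boundaries sit at ranks ceil(k*n/5); ties are broken by
    ascending area id, so the labelling is deterministic and invariant to
    any strictly monotone transform of income.

    Parameters
    ----------
    incomes : pandas.Series
        Median income indexed by area_id.
    scope : iterable of area_id, optional
        Restrict (and label) only these areas.

    Returns
    -------
    pandas.Series of labels in {Q1..Q5}, indexed like the scoped input.
    """
    if scope is not None:
        scope = list(scope)
        if not scope:
            raise ValueError("scope must be non-empty")
        missing = set(map(str, scope)) - set(incomes.index.astype(str))
        if missing:
            raise ValueError(f"incomes missing for scope areas {sorted(missing)}")
        incomes = incomes.loc[scope]
    n = len(incomes)
    if n < 5:
        raise ValueError(f"need at least 5 areas to form quintiles, got {n}")
    order = incomes.reset_index()
    order.columns = ["area_id", "income"]
    order = order.sort_values(["income", "area_id"], kind="mergesort")
    bounds = [int(np.ceil(k * n / 5)) for k in range(6)]
    labels = np.empty(n, dtype=object)
    for k in range(5):
        labels[bounds[k]:bounds[k + 1]] = QUINTILES[k]
    out = pd.Series(labels, index=order["area_id"].values, name="quintile")
    return out.reindex(incomes.index)


def generate_geography(n_rows: int, n_cols: int, income_spatial_trend: float = 0.0,
                       seed: int = 0, *, income_median: float = 220.0,
                       income_sigma: float = 0.2,
                       income_patch_sd: float = 0.0,
                       subareas: Mapping[str, tuple[slice, slice]] | None = None) -> Geography:
    """Generate a rook-adjacency lattice of small areas with incomes.

    Median incomes (thousands of currency units/year) are log-normal around
    ``income_median`` with a smooth west-east gradient: the log-income mean
    increases linearly with the normalised x coordinate, with total slope
    ``income_spatial_trend`` (0 = no spatial structure in income).
    ``income_patch_sd`` adds a spatially autocorrelated (intrinsic-CAR)
    component of that standard deviation to log income, emulating the
    neighbourhood-scale patchiness of deprivation in real urban geographies
    (wealthy and deprived districts interspersed rather than one smooth
    region-wide gradient).

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice dimensions; at least 4 areas in total.
    income_spatial_trend : float
        Log-income difference between the west and east edges.
    income_patch_sd : float
        Standard deviation of the autocorrelated patch component of log
        income (0 = none).
    seed : int
        Seeds the income draw; the lattice itself is deterministic.
    subareas : mapping name -> (row slice, col slice), optional
        Rectangular blocks flagged as named urban subareas.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if n_rows * n_cols < 4:
        raise ValueError("need at least 4 areas")
    rng = np.random.default_rng(seed)
    ndig = len(str(n_rows * n_cols - 1))
    ids = np.array([f"A{idx:0{max(ndig, 4)}d}" for idx in range(n_rows * n_cols)])
    rr, cc = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = cc + 0.5
    y = rr + 0.5
    xn = cc / max(n_cols - 1, 1)
    log_inc = (np.log(income_median) + income_spatial_trend * (xn - xn.mean())
               + rng.normal(0.0, income_sigma, size=ids.size))

    edges = []
    for idx in range(n_rows * n_cols):
        r, c = divmod(idx, n_cols)
        if c + 1 < n_cols:
            edges.append((ids[idx], ids[idx + 1]))
        if r + 1 < n_rows:
            edges.append((ids[idx], ids[idx + n_cols]))

    if income_patch_sd > 0:
        # autocorrelated patch field, rescaled to the requested marginal sd
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(edges)
        L = nx.laplacian_matrix(g, nodelist=list(ids)).toarray().astype(float)
        evals, evecs = np.linalg.eigh(L)
        keep = evals > 1e-9 * evals.max()
        z = rng.standard_normal(int(keep.sum())) / np.sqrt(evals[keep])
        patch = evecs[:, keep] @ z
        log_inc += income_patch_sd * patch / patch.std()

    areas = pd.DataFrame({"x": x, "y": y, "median_income": np.exp(log_inc)}, index=ids)
    areas.index.name = "area_id"
    polys = {ids[idx]: Polygon([(cc[idx], rr[idx]), (cc[idx] + 1, rr[idx]),
                                (cc[idx] + 1, rr[idx] + 1), (cc[idx], rr[idx] + 1)])
             for idx in range(n_rows * n_cols)}
    sub = None
    if subareas:
        grid = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
        sub = {name: [ids[i] for i in grid[rs, cs].ravel()]
               for name, (rs, cs) in subareas.items()}
    return Geography(areas, edges, polygons=polys, subareas=sub)
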