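"""Distance observables, distance maps and conformational state calls.

The conformational fingerprint of a receptor ensemble is summarised by a
small set of named residue-pair distances — e.g. across the tethered-ligand
binding pocket (D256/cg–Y350/oh, Y267/cb–L101/cb) and across the
intracellular effector binding surface (R200/ca–L314/ca, Y290/ca–S375/ca) —
evaluated in every ensemble member.  Their 1D/2D distributions separate
conformational states (constricted vs open pocket, narrow vs extended
effector surface), and a per-model categorical state call is made either by
fixed thresholds or by two-cluster (k=2) partitioning of the pooled values.

Distances are Euclidean and rigid-invariant, so they are computed on
untransformed coordinates; superposition is only needed for overlays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import EnsembleFPError, ResolutionError
from .model_io import Ensemble, StructureModel
from .selection import AtomRef, parse_atomref, resolve_atom

__all__ = [
    "DistancePairSpec",
    "DistanceSeries",
    "DistanceMap2D",
    "StateCall",
    "measure_pair",
    "ensemble_distances",
    "histogram2d",
    "classify_states",
    "select_representative",
]

DEFAULT_BIN_WIDTH = 0.5  # Å; resolves sub-Å structure in the 2D maps


@dataclass(frozen=True)
class DistancePairSpec:
    """A named atom pair; each endpoint carries a chain role resolved to a
    chain id through the run configuration."""

    name: str
    a: AtomRef
    b: AtomRef

    @classmethod
    def from_strings(
        cls,
        a: str,
        b: str,
        role_a: str = "receptor",
        role_b: str = "receptor",
        name: str | None = None,
    ) -> "DistancePairSpec":
        ref_a = parse_atomref(a, chain_role=role_a)
        ref_b = parse_atomref(b, chain_role=role_b)
        return cls(name=name or f"{a}-{b}", a=ref_a, b=ref_b)


@dataclass
class DistanceSeries:
    """One named pair distance evaluated across an ensemble (Å, ordered as
    the ensemble's models)."""

    name: str
    model_ids: list[str]
    values: np.ndarray
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.model_ids),):
            raise ValueError("values length must equal model id count")
        if len(self.values) and (
            not np.isfinite(self.values).all() or (self.values < 0).any()
        ):
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DistanceMap2D:
    """A 2D histogram of two distance series over uniform bins."""

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    model_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if (np.diff(self.x_edges) <= 0).any() or (np.diff(self.y_edges) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.shape != (len(self.x_edges) - 1, len(self.y_edges) - 1):
            raise ValueError("count matrix shape does not match edges")


@dataclass
class StateCall:
    """Per-model categorical conformational label on one or more axes,
    together with the method and parameters that produced it."""

    model_id: str
    states: dict[str, str]
    method: str
    params: dict


def measure_pair(
    model: StructureModel,
    spec: DistancePairSpec,
    roles: Mapping[str, str] | None = None,
) -> float:
    """Euclidean distance (Å) between the two resolved atoms of a pair."""
    roles = roles or {}
    chain_a = roles.get(spec.a.chain_role or "", spec.a.chain_role or "")
    chain_b = roles.get(spec.b.chain_role or "", spec.b.chain_role or "")
    key_a = (chain_a, spec.a.author_resid, spec.a.atom_name)
    key_b = (chain_b, spec.b.author_resid, spec.b.atom_name)
    if key_a == key_b:
        raise ResolutionError(
            f"pair '{spec.name}': both endpoints resolve to the same atom {key_a}"
        )
    try:
        pos_a = resolve_atom(model, chain_a, spec.a)
        pos_b = resolve_atom(model, chain_b, spec.b)
    except ResolutionError as exc:
        raise ResolutionError(f"pair '{spec.name}': {exc}") from exc
    return float(np.linalg.norm(pos_a - pos_b))


def ensemble_distances(
    ens: Ensemble,
    specs: Sequence[DistancePairSpec],
    roles: Mapping[str, str] | None = None,
    skip_unresolvable: bool = False,
) -> list[DistanceSeries]:
    """Evaluate each pair spec across all ensemble members, preserving model
    order.  With ``skip_unresolvable`` a model that fails resolution is
    dropped from that series and recorded; otherwise the first failure
    aborts."""
    out: list[DistanceSeries] = []
    for spec in specs:
        ids: list[str] = []
        values: list[float] = []
        skipped: list[str] = []
        for model in ens.models:
            try:
                d = measure_pair(model, spec, roles)
            except ResolutionError:
                if skip_unresolvable:
                    skipped.append(model.model_id)
                    continue
                raise
            ids.append(model.model_id)
            values.append(d)
        out.append(
            DistanceSeries(
                name=spec.name, model_ids=ids, values=np.array(values), skipped=skipped
            )
        )
    return out


def histogram2d(
    xs: DistanceSeries, ys: DistanceSeries, bin_width: float = DEFAULT_BIN_WIDTH
) -> DistanceMap2D:
    """Bin two distance series on uniform bins spanning
    [floor(min), ceil(max)] padded by one bin on each side; bins are
    right-open except the last (closed), so counts always sum to the number
    of contributing models."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(xs) != len(ys) or xs.model_ids != ys.model_ids:
        raise ValueError(
            f"series '{xs.name}' and '{ys.name}' do not share model order"
        )
    if len(xs) == 0:
        raise ValueError("cannot histogram empty series")

    def edges(values: np.ndarray) -> np.ndarray:
        lo = math.floor(values.min()) - bin_width
        hi = math.ceil(values.max()) + bin_width
        n = max(1, int(round((hi - lo) / bin_width)))
        return lo + bin_width * np.arange(n + 1)

    x_edges = edges(xs.values)
    y_edges = edges(ys.values)
    counts, _, _ = np.histogram2d(xs.values, ys.values, bins=(x_edges, y_edges))
    return DistanceMap2D(
        x_name=xs.name,
        y_name=ys.name,
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts.astype(int),
        model_ids=list(xs.model_ids),
    )


def _axis_matrix(series: Sequence[DistanceSeries]) -> tuple[list[str], np.ndarray]:
    ids = series[0].model_ids
    for s in series[1:]:
        if s.model_ids != ids:
            raise ValueError("series within one axis must share model order")
    return list(ids), np.column_stack([s.values for s in series])


def classify_states(
    series_by_axis: Mapping[str, Sequence[DistanceSeries]],
    method: str = "two-cluster",
    thresholds: Mapping[str, float] | None = None,
    labels: Mapping[str, tuple[str, str]] | None = None,
    random_state: int = 0,
) -> list[StateCall]:
    """Assign each model a categorical state per axis.

    ``two-cluster`` partitions each axis's pooled per-model values (all its
    series as features) with k-means, k=2; the cluster with the smaller mean
    distance receives the first (compact) label, and a separation score
    |μ₁−μ₀| / pooled within-cluster σ is reported in the call parameters.
    ``fixed-threshold`` labels a model by whether its per-axis mean distance
    falls below the configured cut.
    """
    if not series_by_axis:
        raise ValueError("at least one axis is required")
    labels = labels or {}
    params: dict = {"per_axis": {}}
    assignments: dict[str, dict[str, str]] = {}
    model_ids: list[str] | None = None

    for axis, series in series_by_axis.items():
        low, high = labels.get(axis, ("compact", "extended"))
        ids, X = _axis_matrix(list(series))
        if model_ids is None:
            model_ids = ids
        elif ids != model_ids:
            raise ValueError("axes must share model order")
        v = X.mean(axis=1)

        if method == "fixed-threshold":
            if thresholds is None or axis not in thresholds:
                raise ValueError(f"fixed-threshold requires a cut for axis '{axis}'")
            cut = float(thresholds[axis])
            axis_labels = np.where(v < cut, low, high)
            params["per_axis"][axis] = {"threshold": cut}
        elif method == "two-cluster":
            if len(ids) < 4:
                raise EnsembleFPError(
                    f"two-cluster classification needs >= 4 models, got {len(ids)}"
                )
            if np.ptp(X) == 0:
                axis_labels = np.array([low] * len(ids))
                params["per_axis"][axis] = {
                    "cluster_means": [float(v[0]), float(v[0])],
                    "separation": 0.0,
                }
            else:
                km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
                cluster = km.fit_predict(X)
                means = np.array([v[cluster == k].mean() for k in (0, 1)])
                order = np.argsort(means)  # smaller mean -> compact/low label
                name_of = {order[0]: low, order[1]: high}
                axis_labels = np.array([name_of[c] for c in cluster])
                n0, n1 = (cluster == 0).sum(), (cluster == 1).sum()
                s0 = v[cluster == 0].std(ddof=1) if n0 > 1 else 0.0
                s1 = v[cluster == 1].std(ddof=1) if n1 > 1 else 0.0
                pooled = math.sqrt((s0**2 + s1**2) / 2.0)
                sep = abs(means[1] - means[0]) / pooled if pooled > 0 else math.inf
                params["per_axis"][axis] = {
                    "cluster_means": sorted(float(m) for m in means),
                    "separation": float(sep),
                }
        else:
            raise ValueError(f"unknown classification method '{method}'")

        for mid, lab in zip(ids, axis_labels):
            assignments.setdefault(mid, {})[axis] = str(lab)

    assert model_ids is not None
    return [
        StateCall(model_id=mid, states=assignments[mid], method=method, params=params)
        for mid in model_ids
    ]


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(values, edges) - 1
    # last bin is closed on the right
    idx[values == edges[-1]] = len(edges) - 2
    return np.clip(idx, 0, len(edges) - 2)


def select_representative(
    map2d: DistanceMap2D, xs: DistanceSeries, ys: DistanceSeries
) -> str:
    """The model whose (x, y) lies nearest (Euclidean, Å) to the centre of
    the modal (highest-count) bin; ties — between equally occupied bins or
    equally near models — break by model order."""
    if map2d.counts.sum() == 0 or len(xs) == 0:
        raise ValueError("empty distance map")
    if xs.model_ids != ys.model_ids:
        raise ValueError("series do not share model order")
    max_count = map2d.counts.max()
    ix = _bin_index(xs.values, map2d.x_edges)
    iy = _bin_index(ys.values, map2d.y_edges)
    x_centres = 0.5 * (map2d.x_edges[:-1] + map2d.x_edges[1:])
    y_centres = 0.5 * (map2d.y_edges[:-1] + map2d.y_edges[1:])

    best: tuple[float, int] | None = None  # (distance to bin centre, model order)
    for order, (mid, bx, by) in enumerate(zip(xs.model_ids, ix, iy)):
        if map2d.counts[bx, by] != max_count:
            continue
        d = math.hypot(xs.values[order] - x_centres[bx], ys.values[order] - y_centres[by])
        if best is None or (d, order) < best:
            best = (d, order)
    assert best is not None
    return xs.model_ids[best[1]]
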