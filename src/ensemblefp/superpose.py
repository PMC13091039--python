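"""Rigid-body least-squares superposition of ensemble members.

Implements the closed-form (SVD) weighted least-squares fit of one point set
onto another with reflection correction, and applies it ensemble-wide on a
configurable selection — by default the Cα atoms of the receptor
transmembrane (TM) helical bundle, the field-standard frame for comparing
GPCR conformers.

The distance observables computed downstream are invariant to rigid motions,
so superposition matters for overlays and visual comparison, not for the
distance distributions themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryWarning, ResolutionError
from .model_io import Ensemble, StructureModel
from .selection import ResidueRange

__all__ = [
    "RigidTransform",
    "SuperpositionSelection",
    "kabsch_fit",
    "align_ensemble",
    "PAR1_TM_RANGES",
]

ATOM_POLICIES = {
    "ca": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
    "all-heavy": None,  # every atom whose name does not begin with H
}

# Idealised PAR1 seven-helix bundle ranges (author numbering).  A
# package-chosen preset approximating the receptor's TM helices; edit in the
# run configuration for real inputs.
PAR1_TM_RANGES: tuple[tuple[int, int], ...] = (
    (95, 120),
    (130, 155),
    (185, 210),
    (220, 240),
    (262, 292),
    (305, 330),
    (340, 365),
)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: x ↦ R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 within 1e-9")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class SuperpositionSelection:
    """Which atoms define the fit: one chain role, residue ranges, and an
    atom policy (``ca``, ``backbone`` or ``all-heavy``)."""

    chain_role: str = "receptor"
    ranges: tuple[tuple[int, int], ...] = PAR1_TM_RANGES
    atom_policy: str = "ca"

    def __post_init__(self) -> None:
        if self.atom_policy not in ATOM_POLICIES:
            raise ValueError(
                f"unknown atom policy '{self.atom_policy}'; "
                f"expected one of {sorted(ATOM_POLICIES)}"
            )
        object.__setattr__(self, "ranges", tuple(tuple(r) for r in self.ranges))

    def residue_ranges(self) -> list[ResidueRange]:
        return [ResidueRange(self.chain_role, a, b) for a, b in self.ranges]


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal weighted rigid fit of ``mobile`` onto ``reference``.

    Point correspondence is positional.  Returns the proper-rotation
    transform minimising the weighted RMSD and the RMSD (Å) evaluated after
    applying it.  Degenerate configurations (coincident or collinear points)
    still return a transform but raise :class:`DegenerateGeometryWarning`.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"insufficient points for a rigid fit: N={n} < 3")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any():
            raise ValueError("weights must be N non-negative reals")
        if w.sum() <= 0:
            raise ValueError("weights must sum to a positive value")
    wsum = w.sum()

    cm = (w[:, None] * P).sum(axis=0) / wsum
    cq = (w[:, None] * Q).sum(axis=0) / wsum
    Pc = P - cm
    Qc = Q - cq

    H = Pc.T @ (w[:, None] * Qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    scale = max(S[0], 1.0)
    if S[2] <= 1e-8 * scale:
        warnings.warn(
            "degenerate point configuration (coincident or collinear); "
            "the fitted rotation is not unique",
            DegenerateGeometryWarning,
            stacklevel=2,
        )

    t = cq - R @ cm
    transform = RigidTransform(R, t)
    residual = transform.apply(P) - Q
    rmsd = float(np.sqrt((w * (residual**2).sum(axis=1)).sum() / wsum))
    return transform, rmsd


def _selection_keys(
    sel: SuperpositionSelection, model: StructureModel, chain_id: str
) -> list[tuple[int, str]]:
    """Ordered (resid, atom_name) keys the selection resolves to on a model."""
    names = ATOM_POLICIES[sel.atom_policy]
    sub = model.atoms[model.atoms["chain_id"] == chain_id]
    keys: list[tuple[int, str]] = []
    for a, b in sel.ranges:
        block = sub[(sub["author_resid"] >= a) & (sub["author_resid"] <= b)]
        for resid in sorted(block["author_resid"].unique()):
            res_atoms = block[block["author_resid"] == resid]
            for name in sorted(res_atoms["atom_name"].unique()):
                if names is not None and name not in names:
                    continue
                if names is None and name.startswith("H"):
                    continue
                keys.append((int(resid), name))
    return keys


def _coords_for_keys(
    model: StructureModel, chain_id: str, keys: Sequence[tuple[int, str]]
) -> np.ndarray:
    coords = np.empty((len(keys), 3))
    missing: list[tuple[int, str]] = []
    for i, (resid, name) in enumerate(keys):
        rows = model.atom_rows(chain_id, resid, name)
        if rows.empty:
            missing.append((resid, name))
            continue
        # altloc: highest occupancy wins (ties by altloc, 'A' before others)
        rows = rows.sort_values("occupancy", ascending=False, kind="stable")
        coords[i] = rows.iloc[0][["x", "y", "z"]].to_numpy(dtype=float)
    if missing:
        raise ResolutionError(
            f"model {model.model_id}: selection unresolvable, missing "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    return coords


def align_ensemble(
    ens: Ensemble,
    sel: SuperpositionSelection,
    roles: Mapping[str, str] | None = None,
    reference: str = "first",
) -> Ensemble:
    """Superimpose every member on a reference model using the fit computed
    on the selection, carrying each model's full atom set (all chains) along
    with its receptor-fit transform.  The input ensemble is not mutated."""
    if not ens.models:
        raise ResolutionError("cannot align an empty ensemble")
    chain_id = (roles or {}).get(sel.chain_role, sel.chain_role)
    if reference == "first":
        ref_model = ens.models[0]
    else:
        by_id = {m.model_id: m for m in ens.models}
        if reference not in by_id:
            raise ResolutionError(f"reference model '{reference}' not in ensemble")
        ref_model = by_id[reference]

    keys = _selection_keys(sel, ref_model, chain_id)
    if not keys:
        raise ResolutionError("superposition selection is empty on the reference")
    ref_coords = _coords_for_keys(ref_model, chain_id, keys)

    aligned: list[StructureModel] = []
    for model in ens.models:
        if model.model_id == ref_model.model_id:
            aligned.append(model.with_coords(model.coords))
            continue
        mobile = _coords_for_keys(model, chain_id, keys)
        transform, _ = kabsch_fit(mobile, ref_coords)
        aligned.append(model.with_coords(transform.apply(model.coords)))

    return Ensemble(
        label=ens.label,
        models=aligned,
        confidence=dict(ens.confidence),
        provenance=ens.provenance
        + f"; aligned on {sel.chain_role} {sel.atom_policy} selection "
        f"(reference {ref_model.model_id})",
    )
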