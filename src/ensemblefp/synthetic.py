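"""Synthetic two-state model ensembles with full ground truth.

Real inputs to this pipeline are ensembles of predicted receptor (or
receptor–effector) structures plus per-model confidence JSONs.  This module
generates toy ensembles with the same statistical structure — a two-state
conformational mixture with state-dependent interface confidence — so every
pipeline stage can be exercised and verified against known truth without any
structure-prediction service or download.

The receptor is an idealised seven-helix bundle: straight "helical point
chains" with a 1.5 Å rise and 100° turn per residue on a 2.3 Å radius,
author-numbered to match the residue addresses used by the distance pairs
(a geometric stand-in, not a physical model).  An extracellular loop segment
and an intracellular H8 segment complete the receptor; an optional partner
chain (an arrestin finger-loop stand-in) sits at the intracellular face.
Only Cα atoms plus the side-chain atoms needed by the configured pairs are
emitted.

Each model draws a state from a Bernoulli mixture; designated segments are
rigidly displaced by δ in state B; isotropic Gaussian noise is added to all
atoms.  Matching confidence JSONs get a PAE with a state-dependent offset on
the interface token blocks, a state-dependent ipTM drawn from a beta
distribution, and state-dependent pLDDT.  Randomness uses one root seed with
a counter-based substream per model keyed by (seed index, sample index), so
any subset regenerates identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import DistancePairSpec
from .model_io import ATOM_COLUMNS, StructureModel
from .selection import ResidueRange
from .superpose import PAR1_TM_RANGES

__all__ = [
    "SegmentSpec",
    "ConfidenceModel",
    "ToyEnsembleSpec",
    "GroundTruth",
    "generate_ensemble",
    "par1_preset",
    "PAR1_PAIRS",
    "DEFAULT_ROLES",
]

RISE = 1.5  # Å per residue along the segment axis
TURN = math.radians(100.0)  # per residue
HELIX_RADIUS = 2.3  # Å

DEFAULT_ROLES: dict[str, str] = {"receptor": "A", "barr2": "B"}

# The eight distance pairs of the receptor fingerprint: tethered-ligand
# pocket, effector binding surface, and the receptor-core / arrestin
# finger-loop interface.
PAR1_PAIRS: tuple[tuple[str, str, str, str], ...] = (
    ("D256^45.52/cg", "Y350^7.32/oh", "receptor", "receptor"),
    ("Y267^5.35/cb", "L101^1.31/cb", "receptor", "receptor"),
    ("R200^3.50/ca", "L314^6.36/ca", "receptor", "receptor"),
    ("Y290^5.58/ca", "S375^8.47/ca", "receptor", "receptor"),
    ("K135^2.37/cb", "R66/cb", "receptor", "barr2"),
    ("K135^2.37/cb", "V71/cb", "receptor", "barr2"),
    ("A374^7.56/cb", "R66/cb", "receptor", "barr2"),
    ("A374^7.56/cb", "V71/cb", "receptor", "barr2"),
)


def par1_pair_specs() -> list[DistancePairSpec]:
    return [
        DistancePairSpec.from_strings(a, b, role_a=ra, role_b=rb)
        for a, b, ra, rb in PAR1_PAIRS
    ]


@dataclass(frozen=True)
class SegmentSpec:
    """One straight helical point-chain segment."""

    name: str
    chain: str
    start: int
    end: int
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConfidenceModel:
    """Parameters of the state-dependent confidence generator."""

    pae_base: float = 12.0
    interface_offset_state_a: float = -6.0
    interface_offset_state_b: float = 0.0
    pae_noise_sigma: float = 0.3
    pae_diag: float = 0.8
    pae_min: float = 0.25
    pae_max: float = 31.75
    iptm_beta_a: tuple[float, float] = (40.0, 10.0)
    iptm_beta_b: tuple[float, float] = (15.0, 15.0)
    plddt_mean_a: float = 88.0
    plddt_mean_b: float = 78.0
    plddt_sigma: float = 4.0
    interface_motif: ResidueRange = ResidueRange("barr2", 64, 77)
    interface_partner_role: str = "receptor"


@dataclass
class ToyEnsembleSpec:
    """Everything needed to generate a two-state toy ensemble."""

    n_seeds: int = 20
    models_per_seed: int = 5
    segments: tuple[SegmentSpec, ...] = ()
    residue_names: Mapping[tuple[str, int], str] = field(default_factory=dict)
    extra_atoms: Mapping[tuple[str, int], tuple[tuple[str, float], ...]] = field(
        default_factory=dict
    )
    state_b_shifts: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    mixture_weight: float = 0.5  # fraction of models in state A
    noise_sigma: float = 0.8  # Å, per-atom isotropic
    confidence: ConfidenceModel = field(default_factory=ConfidenceModel)
    pairs: tuple[tuple[str, str, str, str], ...] = PAR1_PAIRS
    roles: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    rng_seed: int = 0

    @property
    def n_models(self) -> int:
        return self.n_seeds * self.models_per_seed

    def validate(self) -> None:
        if self.n_seeds < 1 or self.models_per_seed < 1:
            raise ValidationError("seed scheme must be positive")
        if not (0.0 <= self.mixture_weight <= 1.0):
            raise ValidationError("mixture_weight must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not self.segments:
            raise ValidationError("at least one segment is required")
        for shifts in self.state_b_shifts.values():
            if len(shifts) != 3:
                raise ValidationError("state_b_shifts entries must be 3-vectors")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValidationError("segment names must be unique")
        unknown = set(self.state_b_shifts) - set(names)
        if unknown:
            raise ValidationError(f"state_b_shifts reference unknown segments {unknown}")

    def pair_specs(self) -> list[DistancePairSpec]:
        return [
            DistancePairSpec.from_strings(a, b, role_a=ra, role_b=rb)
            for a, b, ra, rb in self.pairs
        ]


@dataclass
class GroundTruth:
    """Generator-side truth for every emitted model."""

    states: dict[str, str]
    true_distances: dict[str, dict[str, float]]  # model -> pair -> Å (pre-noise)
    confidence_params: dict[str, dict]
    mixture_weight: float
    state_a_count: int
    atom_count: int  # atoms per model


# ---------------------------------------------------------------------------
# Template geometry
# ---------------------------------------------------------------------------


def _orthonormal_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def template_atoms(spec: ToyEnsembleSpec, state: str) -> pd.DataFrame:
    """Noise-free atom table for one conformational state ('A' or 'B')."""
    rows: list[tuple] = []
    for seg in spec.segments:
        origin = np.asarray(seg.origin, dtype=float)
        direction = np.asarray(seg.direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        if state == "B" and seg.name in spec.state_b_shifts:
            origin = origin + np.asarray(spec.state_b_shifts[seg.name], dtype=float)
        u, v = _orthonormal_frame(direction)
        for i, resid in enumerate(range(seg.start, seg.end + 1)):
            radial = math.cos(TURN * i) * u + math.sin(TURN * i) * v
            ca = origin + RISE * i * direction + HELIX_RADIUS * radial
            resname = spec.residue_names.get((seg.chain, resid), "ALA")
            rows.append(
                (seg.chain, resid, resname, "CA", "", ca[0], ca[1], ca[2], 1.0, 0.0)
            )
            for atom_name, dist in spec.extra_atoms.get((seg.chain, resid), ()):
                pos = ca + dist * radial
                rows.append(
                    (
                        seg.chain,
                        resid,
                        resname,
                        atom_name,
                        "",
                        pos[0],
                        pos[1],
                        pos[2],
                        1.0,
                        0.0,
                    )
                )
    frame = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    # chain/residue order as a reader expects; stable, so CA precedes the
    # side-chain atoms within each residue
    return frame.sort_values(
        ["chain_id", "author_resid"], kind="stable", ignore_index=True
    )


def _template_model(spec: ToyEnsembleSpec, state: str) -> StructureModel:
    return StructureModel(model_id=f"template-{state}", atoms=template_atoms(spec, state))


def template_distances(spec: ToyEnsembleSpec, state: str) -> dict[str, float]:
    """Exact pre-noise distances of every configured pair in one state."""
    from .geometry import measure_pair  # local import to avoid cycle at import time

    model = _template_model(spec, state)
    return {
        ps.name: measure_pair(model, ps, spec.roles) for ps in spec.pair_specs()
    }


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

_ELEMENT_OF = {"O": "O", "N": "N", "S": "S"}


def _write_mmcif(
    atoms: pd.DataFrame, plddt: Mapping[tuple[str, int], float], path: Path
) -> None:
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model(1)
    chain: gemmi.Chain | None = None
    residue: gemmi.Residue | None = None
    current: tuple[str, int] | None = None
    cols = (
        atoms["chain_id"],
        atoms["author_resid"],
        atoms["residue_name"],
        atoms["atom_name"],
        atoms["x"],
        atoms["y"],
        atoms["z"],
        atoms["occupancy"],
    )
    for chain_id, resid, resname, atom_name, x, y, z, occ in zip(*cols):
        resid = int(resid)
        if chain is None or chain.name != chain_id:
            chain = model.add_chain(gemmi.Chain(str(chain_id)))
            current = None
        if current != (chain_id, resid):
            new_res = gemmi.Residue()
            new_res.name = str(resname)
            new_res.seqid = gemmi.SeqId(resid, " ")
            residue = chain.add_residue(new_res)
            current = (chain_id, resid)
        atom = gemmi.Atom()
        atom.name = str(atom_name)
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = float(occ)
        atom.b_iso = float(plddt.get((chain_id, resid), 0.0))
        atom.element = gemmi.Element(_ELEMENT_OF.get(str(atom_name)[:1], "C"))
        residue.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


def _token_layout(spec: ToyEnsembleSpec) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for seg in spec.segments:
        for resid in range(seg.start, seg.end + 1):
            key = (seg.chain, resid)
            if key not in seen:
                seen.add(key)
                tokens.append(key)
    # group by chain in order of first appearance, as AF3 tokens are
    chains = list(dict.fromkeys(c for c, _ in tokens))
    return [t for c in chains for t in sorted((x for x in tokens if x[0] == c), key=lambda x: x[1])]


def _confidence_payload(
    spec: ToyEnsembleSpec, state: str, rng: np.random.Generator
) -> tuple[dict, dict, dict]:
    """(summary json, full json, declared parameters) for one model."""
    cm = spec.confidence
    tokens = _token_layout(spec)
    n = len(tokens)
    pae = cm.pae_base + rng.normal(0.0, cm.pae_noise_sigma, size=(n, n))

    offset = (
        cm.interface_offset_state_a if state == "A" else cm.interface_offset_state_b
    )
    motif_chain = spec.roles.get(
        cm.interface_motif.chain_role, cm.interface_motif.chain_role
    )
    partner_chain = spec.roles.get(cm.interface_partner_role, cm.interface_partner_role)
    motif_idx = [
        i
        for i, (c, r) in enumerate(tokens)
        if c == motif_chain and cm.interface_motif.start <= r <= cm.interface_motif.end
    ]
    partner_idx = [i for i, (c, _) in enumerate(tokens) if c == partner_chain]
    if motif_idx and partner_idx:
        pae[np.ix_(motif_idx, partner_idx)] += offset
        pae[np.ix_(partner_idx, motif_idx)] += offset
    np.fill_diagonal(pae, cm.pae_diag)
    pae = np.clip(pae, cm.pae_min, cm.pae_max)
    pae = np.round(pae, 2)

    plddt_mean = cm.plddt_mean_a if state == "A" else cm.plddt_mean_b
    plddt = np.clip(rng.normal(plddt_mean, cm.plddt_sigma, size=n), 0.0, 100.0)
    plddt = np.round(plddt, 2)

    a, b = cm.iptm_beta_a if state == "A" else cm.iptm_beta_b
    iptm = round(float(rng.beta(a, b)), 3)

    chain_ids = list(dict.fromkeys(c for c, _ in tokens))
    pair_matrix = [
        [iptm if i != j else 0.95 for j in range(len(chain_ids))]
        for i in range(len(chain_ids))
    ]
    summary = {
        "iptm": iptm,
        "ptm": iptm,
        "chain_ids": chain_ids,
        "chain_pair_iptm": pair_matrix,
    }
    full = {
        "pae": pae.tolist(),
        "plddt": plddt.tolist(),
        "token_chain_ids": [c for c, _ in tokens],
        "token_res_ids": [r for _, r in tokens],
    }
    declared = {
        "state": state,
        "iptm": iptm,
        "interface_pae_offset": offset,
        "plddt_mean_target": plddt_mean,
        "plddt_by_residue": {f"{c}:{r}": p for (c, r), p in zip(tokens, plddt)},
    }
    return summary, full, declared


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_ensemble(
    spec: ToyEnsembleSpec,
    out_dir: str | Path,
    rng_seed: int | None = None,
) -> GroundTruth:
    """Write a full toy ensemble (coordinate mmCIFs + confidence JSONs +
    ground-truth files) under ``out_dir`` and return its ground truth.

    Deterministic for a given seed: model (s, j) uses the substream
    ``default_rng([seed, s, j])``, so regeneration — of the whole ensemble or
    any subset — is byte-identical.
    """
    spec.validate()
    root_seed = spec.rng_seed if rng_seed is None else rng_seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    templates = {s: template_atoms(spec, s) for s in ("A", "B")}
    truth_distances = {s: template_distances(spec, s) for s in ("A", "B")}

    states: dict[str, str] = {}
    per_model_truth: dict[str, dict[str, float]] = {}
    conf_params: dict[str, dict] = {}
    atom_count = len(templates["A"])

    for s in range(spec.n_seeds):
        for j in range(spec.models_per_seed):
            rng = np.random.default_rng([root_seed, s, j])
            state = "A" if rng.random() < spec.mixture_weight else "B"
            model_id = f"seed-{s:03d}_sample-{j}"
            states[model_id] = state
            per_model_truth[model_id] = dict(truth_distances[state])

            atoms = templates[state].copy()
            noise = rng.normal(0.0, spec.noise_sigma, size=(len(atoms), 3))
            atoms[["x", "y", "z"]] = atoms[["x", "y", "z"]].to_numpy() + noise

            summary, full, declared = _confidence_payload(spec, state, rng)
            conf_params[model_id] = {
                k: v for k, v in declared.items() if k != "plddt_by_residue"
            }

            plddt_by_res = {
                (key.split(":")[0], int(key.split(":")[1])): val
                for key, val in declared["plddt_by_residue"].items()
            }
            _write_mmcif(atoms, plddt_by_res, out / f"{model_id}_model.cif")
            with open(out / f"{model_id}_summary_confidences.json", "w") as fh:
                json.dump(summary, fh)
            with open(out / f"{model_id}_full_data.json", "w") as fh:
                json.dump(full, fh)

    truth = GroundTruth(
        states=states,
        true_distances=per_model_truth,
        confidence_params=conf_params,
        mixture_weight=spec.mixture_weight,
        state_a_count=sum(1 for s in states.values() if s == "A"),
        atom_count=atom_count,
    )

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "states": truth.states,
                "true_distances": truth.true_distances,
                "confidence_params": truth.confidence_params,
                "mixture_weight": truth.mixture_weight,
                "state_a_count": truth.state_a_count,
                "atom_count": truth.atom_count,
                "rng_seed": root_seed,
            },
            fh,
            indent=1,
        )
    pd.DataFrame(
        {
            "model_id": list(truth.states),
            "state": list(truth.states.values()),
        }
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# Preset
# ---------------------------------------------------------------------------


def par1_preset(
    n_seeds: int = 20,
    models_per_seed: int = 5,
    delta: float = 8.0,
    noise_sigma: float = 0.8,
    mixture_weight: float = 0.5,
    rng_seed: int = 0,
    with_partner: bool = True,
) -> ToyEnsembleSpec:
    """Toy receptor (+ arrestin finger-loop partner) preset.

    Seven TM helices whose residue ranges match the TM superposition preset,
    an extracellular-loop segment dipping into the pocket mouth (carrying
    D256), an H8 segment carrying A374/S375, and a partner chain carrying
    the finger-loop residues (R66/V71, motif 64–77).  In state B the TM7/H8
    block is displaced by δ along +x (opening the pocket and widening the
    effector surface), TM6 by δ along −y, and the partner chain by δ along
    +y; the displacement directions are chosen along the respective pair
    vectors so the designated pairs (D256–Y350, R200–L314, Y290–S375)
    separate by order δ between states.
    """
    bundle_r = 10.0
    segs: list[SegmentSpec] = []
    tm_names = [f"TM{i}" for i in range(1, 8)]
    for k, ((a, b), name) in enumerate(zip(PAR1_TM_RANGES, tm_names)):
        angle = 2.0 * math.pi * k / 7.0
        axis = (bundle_r * math.cos(angle), bundle_r * math.sin(angle))
        if k % 2 == 0:  # odd-numbered TMs run extracellular -> intracellular
            origin = (axis[0], axis[1], 16.0)
            direction = (0.0, 0.0, -1.0)
        else:
            origin = (axis[0], axis[1], -16.0)
            direction = (0.0, 0.0, 1.0)
        segs.append(SegmentSpec(name, "A", a, b, origin, direction))
    # extracellular loop dipping into the pocket mouth near the TM7 top
    segs.append(
        SegmentSpec("ECL2", "A", 250, 260, (-4.0, -12.0, 3.0), (1.0, 0.0, 0.0))
    )
    # intracellular helix 8, leaving the TM7 bottom
    segs.append(
        SegmentSpec("H8", "A", 368, 380, (8.0, -4.0, -18.0), (0.0, -1.0, 0.0))
    )
    if with_partner:
        segs.append(
            SegmentSpec("FLR", "B", 58, 82, (4.0, -6.0, -22.0), (1.0, 0.0, 0.0))
        )

    residue_names = {
        ("A", 101): "LEU",
        ("A", 135): "LYS",
        ("A", 200): "ARG",
        ("A", 256): "ASP",
        ("A", 267): "TYR",
        ("A", 290): "TYR",
        ("A", 314): "LEU",
        ("A", 350): "TYR",
        ("A", 374): "ALA",
        ("A", 375): "SER",
        ("B", 66): "ARG",
        ("B", 71): "VAL",
    }
    extra_atoms = {
        ("A", 101): (("CB", 1.5),),
        ("A", 135): (("CB", 1.5),),
        ("A", 256): (("CB", 1.5), ("CG", 2.6)),
        ("A", 267): (("CB", 1.5),),
        ("A", 350): (("CB", 1.5), ("OH", 4.2)),
        ("A", 374): (("CB", 1.5),),
        ("B", 66): (("CB", 1.5),),
        ("B", 71): (("CB", 1.5),),
    }
    shifts = {
        "TM6": (0.0, -delta, 0.0),
        "TM7": (delta, 0.0, 0.0),
        "H8": (delta, 0.0, 0.0),
    }
    if with_partner:
        shifts["FLR"] = (0.0, delta, 0.0)

    pairs = PAR1_PAIRS if with_partner else PAR1_PAIRS[:4]
    return ToyEnsembleSpec(
        n_seeds=n_seeds,
        models_per_seed=models_per_seed,
        segments=tuple(segs),
        residue_names=residue_names,
        extra_atoms=extra_atoms,
        state_b_shifts=shifts,
        mixture_weight=mixture_weight,
        noise_sigma=noise_sigma,
        pairs=pairs,
        rng_seed=rng_seed,
    )
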