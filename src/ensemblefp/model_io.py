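"""Structure and confidence I/O.

Reads predicted coordinate files (mmCIF/PDB, via gemmi) and AF3-server-style
confidence JSONs into the package's in-memory data model, assembles seed-batch
directories into :class:`Ensemble` objects, and writes tabular results.

Conventions
-----------
* Residues are addressed by *author* numbering (1-based, inclusive ranges),
  the numbering used throughout the receptor-pharmacology literature
  ("amino acids 64–77" style).
* Atom names are normalised to uppercase PDB convention (CA, CB, CG, OH).
* Alternate locations are retained at read time; downstream resolution picks
  the highest-occupancy record (ties: altloc 'A', then lexical order).
* PAE matrices are stored exactly as found in the JSON: entry (i, j) is the
  expected position error of token j when the prediction is aligned on token
  i.  Any symmetrisation is an explicit downstream option.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

try:  # gemmi is a hard dependency; guard only to give a clear message
    import gemmi
except ImportError as _exc:  # pragma: no cover
    raise ImportError("ensemblefp requires gemmi for mmCIF/PDB I/O") from _exc

from .errors import CompositionError, DimensionError, ParseError

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ConfidenceBundle",
    "Ensemble",
    "EnsembleManifest",
    "read_model",
    "read_confidence",
    "load_ensemble",
    "write_tables",
]

ATOM_COLUMNS = [
    "chain_id",
    "author_resid",
    "residue_name",
    "atom_name",
    "altloc",
    "x",
    "y",
    "z",
    "occupancy",
    "bfactor",
]

# Accepted key aliases in AF3-style JSON files.
PLDDT_KEYS = ("plddt", "token_plddts")
PAE_KEYS = ("pae", "predicted_aligned_error")
IPTM_KEYS = ("iptm",)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position (Å) and the per-atom B-factor column
    (which carries per-atom pLDDT in predicted structures)."""

    chain_id: str
    author_resid: int
    residue_name: str
    atom_name: str
    altloc: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0


@dataclass
class StructureModel:
    """A single predicted model: a table of atoms addressed by
    (chain, author residue number, atom name, altloc)."""

    model_id: str
    atoms: pd.DataFrame
    seed: int | None = None
    sample_index: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        self.atoms = self.atoms.reset_index(drop=True)

    # ---- views -----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """N×3 coordinate array (Å), copy-safe to transform."""
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        """Chain ids in order of first appearance."""
        return list(dict.fromkeys(self.atoms["chain_id"]))

    @property
    def chain_sequences(self) -> dict[str, list[tuple[int, str]]]:
        """Per-chain ordered (author_resid, residue_name) list."""
        out: dict[str, list[tuple[int, str]]] = {}
        for chain in self.chain_ids:
            sub = self.atoms[self.atoms["chain_id"] == chain]
            seen: dict[int, str] = {}
            for resid, resname in zip(sub["author_resid"], sub["residue_name"]):
                seen.setdefault(int(resid), str(resname))
            out[chain] = sorted(seen.items())
        return out

    def residue_name_of(self, chain_id: str, author_resid: int) -> str | None:
        sub = self.atoms[
            (self.atoms["chain_id"] == chain_id)
            & (self.atoms["author_resid"] == author_resid)
        ]
        if sub.empty:
            return None
        return str(sub["residue_name"].iloc[0])

    def atom_rows(self, chain_id: str, author_resid: int, atom_name: str) -> pd.DataFrame:
        """All records (altlocs) matching (chain, resid, atom name)."""
        return self.atoms[
            (self.atoms["chain_id"] == chain_id)
            & (self.atoms["author_resid"] == author_resid)
            & (self.atoms["atom_name"] == atom_name)
        ]

    def iter_atoms(self) -> Iterator[AtomRecord]:
        for row in self.atoms.itertuples(index=False):
            yield AtomRecord(
                chain_id=row.chain_id,
                author_resid=int(row.author_resid),
                residue_name=row.residue_name,
                atom_name=row.atom_name,
                altloc=row.altloc,
                position=np.array([row.x, row.y, row.z], dtype=float),
                occupancy=float(row.occupancy),
                bfactor=float(row.bfactor),
            )

    # ---- invariants ------------------------------------------------------

    def validate(self) -> None:
        xyz = self.coords
        if not np.isfinite(xyz).all():
            raise ParseError(f"{self.model_id}: non-finite coordinates")
        keys = list(
            zip(
                self.atoms["chain_id"],
                self.atoms["author_resid"],
                self.atoms["atom_name"],
                self.atoms["altloc"],
            )
        )
        if len(set(keys)) != len(keys):
            dup = pd.Series(keys).value_counts()
            offender = dup.index[0]
            raise ParseError(
                f"{self.model_id}: uniqueness violation — duplicated atom key "
                f"(chain, resid, atom, altloc) = {offender}"
            )

    # ---- geometry --------------------------------------------------------

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy of this model with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = coords
        return StructureModel(
            model_id=self.model_id,
            atoms=atoms,
            seed=self.seed,
            sample_index=self.sample_index,
        )


@dataclass
class ConfidenceBundle:
    """Per-model confidence: pLDDT vector, PAE matrix, ipTM scalar(s) and a
    token index map keyed by (chain_id, author_resid)."""

    plddt: np.ndarray
    pae: np.ndarray
    iptm: float
    tokens: list[tuple[str, int]]
    chain_pair_iptm: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = len(self.tokens)
        if self.pae.shape != (n, n):
            raise DimensionError(
                f"PAE matrix {self.pae.shape} does not match token count {n}"
            )
        if self.plddt.shape != (n,):
            raise DimensionError(
                f"pLDDT length {self.plddt.shape} does not match token count {n}"
            )
        self._index = {tok: i for i, tok in enumerate(self.tokens)}
        if len(self._index) != n:
            raise DimensionError("token map is not a bijection (duplicate tokens)")

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def token_index(self, chain_id: str, author_resid: int) -> int:
        return self._index[(chain_id, int(author_resid))]

    def has_token(self, chain_id: str, author_resid: int) -> bool:
        return (chain_id, int(author_resid)) in self._index


@dataclass
class Ensemble:
    """A labelled, ordered collection of models sharing chain composition,
    with optional per-model confidence bundles."""

    label: str
    models: list[StructureModel]
    confidence: dict[str, ConfidenceBundle] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.models)

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]

    def validate(self) -> None:
        if not self.models:
            raise CompositionError(f"ensemble '{self.label}' is empty")
        ids = self.model_ids
        if len(set(ids)) != len(ids):
            raise CompositionError(f"ensemble '{self.label}' has duplicate model ids")
        ref = self.models[0]
        ref_seq = {c: [r for r, _ in rs] for c, rs in ref.chain_sequences.items()}
        for m in self.models:
            seq = {c: [r for r, _ in rs] for c, rs in m.chain_sequences.items()}
            if set(seq) != set(ref_seq):
                raise CompositionError(
                    f"model '{m.model_id}' chain set {sorted(seq)} differs from "
                    f"reference {sorted(ref_seq)}"
                )
            for c in ref_seq:
                if seq[c] != ref_seq[c]:
                    raise CompositionError(
                        f"model '{m.model_id}' chain {c} residue range differs "
                        f"from reference model '{ref.model_id}'"
                    )


# ---------------------------------------------------------------------------
# Coordinate file reading
# ---------------------------------------------------------------------------


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    raise ParseError(f"cannot infer coordinate dialect from '{path.name}'")


def read_model(
    path: str | os.PathLike,
    dialect: str = "auto",
    model_id: str | None = None,
    residue_offsets: Mapping[str, int] | None = None,
) -> StructureModel:
    """Read one coordinate file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        mmCIF or PDB file. Only the atom records are used (anisotropic
        records and assembly annotations are ignored).
    dialect
        ``"mmcif"``, ``"pdb"`` or ``"auto"`` (by file extension).
    model_id
        Identifier for the model; defaults to the file stem.
    residue_offsets
        Optional per-chain integer added to every author residue number at
        read time, for inputs whose numbering was shifted upstream.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in ("mmcif", "pdb"):
        raise ParseError(f"unknown dialect '{dialect}'")
    fmt = gemmi.CoorFormat.Mmcif if dialect == "mmcif" else gemmi.CoorFormat.Pdb
    try:
        structure = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path.name}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{path.name}: no models in file")

    offsets = dict(residue_offsets or {})
    rows: list[tuple] = []
    gmodel = structure[0]
    for chain in gmodel:
        off = offsets.get(chain.name, 0)
        for residue in chain:
            for atom in residue:
                altloc = atom.altloc if atom.altloc != "\0" else ""
                rows.append(
                    (
                        chain.name,
                        residue.seqid.num + off,
                        residue.name.upper(),
                        atom.name.upper(),
                        altloc,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.occ,
                        atom.b_iso,
                    )
                )
    if not rows:
        raise ParseError(f"{path.name}: empty atom list")
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    model = StructureModel(model_id=model_id or path.stem, atoms=atoms)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Confidence JSON reading
# ---------------------------------------------------------------------------


def _first_key(d: Mapping, keys: Sequence[str]):
    for k in keys:
        if k in d:
            return d[k]
    return None


def _model_tokens(model: StructureModel) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    for chain, residues in model.chain_sequences.items():
        tokens.extend((chain, resid) for resid, _ in residues)
    return tokens


def read_confidence(
    summary_path: str | os.PathLike,
    full_path: str | os.PathLike,
    model: StructureModel,
) -> ConfidenceBundle:
    """Read an AF3-server-layout confidence pair (summary + full data JSON)
    for a given model.

    The PAE matrix is stored exactly as found in the JSON — no symmetrisation
    or reordering.  The token map is taken from ``token_chain_ids`` /
    ``token_res_ids`` when the full-data JSON carries them, otherwise it is
    constructed from the model's chain order and residue order.
    """
    with open(summary_path) as fh:
        summary = json.load(fh)
    with open(full_path) as fh:
        full = json.load(fh)

    missing = [k for k in IPTM_KEYS if k not in summary]
    if missing:
        raise ParseError(
            f"{Path(summary_path).name}: missing required keys {missing}"
        )
    iptm = float(summary["iptm"])

    pae = _first_key(full, PAE_KEYS)
    if pae is None:
        raise ParseError(
            f"{Path(full_path).name}: no PAE matrix under any of {list(PAE_KEYS)}"
        )
    pae = np.asarray(pae, dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise DimensionError(f"PAE matrix is not square: {pae.shape}")

    if "token_chain_ids" in full and "token_res_ids" in full:
        tokens = [
            (str(c), int(r))
            for c, r in zip(full["token_chain_ids"], full["token_res_ids"])
        ]
    else:
        tokens = _model_tokens(model)

    n_model = sum(len(v) for v in model.chain_sequences.values())
    if pae.shape[0] != n_model:
        raise DimensionError(
            f"PAE side {pae.shape[0]} does not match model residue count {n_model}"
        )
    if len(tokens) != pae.shape[0]:
        raise DimensionError(
            f"token list length {len(tokens)} does not match PAE side {pae.shape[0]}"
        )

    plddt = _first_key(full, PLDDT_KEYS)
    if plddt is None:
        plddt = _first_key(summary, PLDDT_KEYS)
    if plddt is None:
        raise ParseError(
            f"{Path(full_path).name}: no per-token pLDDT under any of {list(PLDDT_KEYS)}"
        )

    chain_pair: dict[tuple[str, str], float] | None = None
    if "chain_pair_iptm" in summary:
        matrix = summary["chain_pair_iptm"]
        chain_ids = summary.get("chain_ids") or model.chain_ids
        if len(matrix) != len(chain_ids):
            raise DimensionError(
                "chain_pair_iptm side does not match chain count"
            )
        chain_pair = {
            (str(a), str(b)): float(matrix[i][j])
            for i, a in enumerate(chain_ids)
            for j, b in enumerate(chain_ids)
        }

    return ConfidenceBundle(
        plddt=np.asarray(plddt, dtype=float),
        pae=pae,
        iptm=iptm,
        tokens=tokens,
        chain_pair_iptm=chain_pair,
    )


# ---------------------------------------------------------------------------
# Ensemble loading
# ---------------------------------------------------------------------------


@dataclass
class EnsembleManifest:
    """Naming scheme that maps files in a directory to ensemble members.

    ``model_pattern`` is a regex matched against each file's path relative to
    the root (POSIX separators); named groups ``seed`` and ``sample`` order
    the ensemble.  Confidence files are located by replacing the model-file
    tail (``model_tail``) with the summary/full suffixes.
    """

    model_pattern: str = r"seed-(?P<seed>\d+)_sample-(?P<sample>\d+)_model\.(?:cif|pdb)$"
    model_tail: str = "_model"
    summary_suffix: str = "_summary_confidences.json"
    full_suffix: str = "_full_data.json"

    def confidence_paths(self, model_path: Path) -> tuple[Path, Path]:
        stem = model_path.name
        stem = stem[: stem.rfind(self.model_tail)] if self.model_tail in stem else model_path.stem
        return (
            model_path.with_name(stem + self.summary_suffix),
            model_path.with_name(stem + self.full_suffix),
        )


def load_ensemble(
    root: str | os.PathLike,
    manifest: EnsembleManifest | None = None,
    label: str | None = None,
    residue_offsets: Mapping[str, int] | None = None,
) -> Ensemble:
    """Assemble every model matching the manifest under ``root`` into an
    :class:`Ensemble`, ordered by (seed, sample index), attaching confidence
    bundles where the matching JSON files exist."""
    root = Path(root)
    manifest = manifest or EnsembleManifest()
    pattern = re.compile(manifest.model_pattern)

    matches: list[tuple[int, int, Path]] = []
    for p in sorted(root.rglob("*")):
        if not p.is_file():
            continue
        m = pattern.search(p.relative_to(root).as_posix())
        if m:
            groups = m.groupdict()
            seed = int(groups.get("seed") or 0)
            sample = int(groups.get("sample") or 0)
            matches.append((seed, sample, p))
    if not matches:
        raise CompositionError(
            f"no files under {root} match pattern '{manifest.model_pattern}'"
        )
    matches.sort(key=lambda t: (t[0], t[1], t[2].name))

    models: list[StructureModel] = []
    confidence: dict[str, ConfidenceBundle] = {}
    for seed, sample, path in matches:
        model = read_model(
            path,
            model_id=f"seed-{seed:03d}_sample-{sample}",
            residue_offsets=residue_offsets,
        )
        model.seed = seed
        model.sample_index = sample
        models.append(model)
        summary_path, full_path = manifest.confidence_paths(path)
        if summary_path.exists() and full_path.exists():
            confidence[model.model_id] = read_confidence(summary_path, full_path, model)

    ensemble = Ensemble(
        label=label or root.name,
        models=models,
        confidence=confidence,
        provenance=f"loaded from {root} ({len(models)} models)",
    )
    ensemble.validate()
    return ensemble


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tables(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    run_info: Mapping | None = None,
) -> dict[str, str]:
    """Write each result table as a TSV (fixed column order, as given) plus an
    optional ``run_summary.json``; all writes are atomic so a rerun cleanly
    overwrites.  Returns a name → path manifest."""
    if not results:
        raise ValueError("no result tables to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in results.items():
        path = out / f"{name}.tsv"
        _atomic_write(path, table.to_csv(sep="\t", index=False))
        manifest[name] = str(path)
    if run_info is not None:
        path = out / "run_summary.json"
        _atomic_write(path, json.dumps(dict(run_info), indent=2, sort_keys=True) + "\n")
        manifest["run_summary"] = str(path)
    return manifest
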