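"""Compact atom addressing and residue-range selection.

The receptor literature names atoms with a compact notation like
``D256^45.52/cg``: one-letter residue type, author residue number, an
optional Ballesteros–Weinstein (BW) position code after ``^``, and the atom
name after ``/``.  This module parses that notation, resolves references to
concrete atoms in a model (applying the alternate-location policy), and maps
author-numbered residue ranges to confidence-matrix token positions.

BW codes are carried as annotations only; resolution is always by author
residue number plus atom name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping

import gemmi
import numpy as np

from .errors import CoverageError, ParseError, ResolutionError
from .model_io import ConfidenceBundle, StructureModel

__all__ = [
    "AtomRef",
    "ResidueRange",
    "BWMap",
    "parse_atomref",
    "format_atomref",
    "resolve_atom",
    "range_to_tokens",
]

_ATOMREF_GRAMMAR = "LETTER? DIGITS ('^' BW)? '/' ATOM   e.g. D256^45.52/cg or R66/cb"
_ATOMREF_RE = re.compile(
    r"^(?P<letter>[A-Za-z])?(?P<resid>\d+)(?:\^(?P<bw>\d+\.\d+))?/(?P<atom>[A-Za-z][A-Za-z0-9']*)$"
)


@dataclass(frozen=True)
class AtomRef:
    """A single atom address in compact notation, before chain resolution."""

    author_resid: int
    atom_name: str
    residue_letter: str | None = None
    bw_code: str | None = None
    chain_role: str | None = None

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.author_resid < 1:
            raise ValueError("author_resid must be >= 1")


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue range on one chain role."""

    chain_role: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"range start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class BWMap:
    """Author residue number → Ballesteros–Weinstein code for one receptor."""

    mapping: Mapping[int, str]

    def __post_init__(self) -> None:
        codes = list(self.mapping.values())
        if len(set(codes)) != len(codes):
            raise ValueError("BW map is not injective")

    def bw_of(self, author_resid: int) -> str | None:
        return self.mapping.get(author_resid)

    def annotate(self, ref: AtomRef) -> AtomRef:
        return replace(ref, bw_code=self.bw_of(ref.author_resid))


def parse_atomref(text: str, chain_role: str | None = None) -> AtomRef:
    """Parse compact notation like ``D256^45.52/cg`` into an :class:`AtomRef`.

    The atom field is case-insensitive and normalised to uppercase; the
    residue letter and BW code are optional.
    """
    m = _ATOMREF_RE.match(text.strip())
    if not m:
        raise ParseError(
            f"cannot parse atom address '{text}'; expected {_ATOMREF_GRAMMAR}"
        )
    return AtomRef(
        author_resid=int(m["resid"]),
        atom_name=m["atom"].upper(),
        residue_letter=m["letter"].upper() if m["letter"] else None,
        bw_code=m["bw"],
        chain_role=chain_role,
    )


def format_atomref(ref: AtomRef) -> str:
    """Canonical compact form: uppercase residue letter, lowercase atom."""
    letter = ref.residue_letter or ""
    bw = f"^{ref.bw_code}" if ref.bw_code else ""
    return f"{letter}{ref.author_resid}{bw}/{ref.atom_name.lower()}"


def _one_letter(residue_name: str) -> str | None:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None:
        return None
    code = info.one_letter_code.upper()
    return code if code.isalpha() else None


def resolve_atom(model: StructureModel, chain_id: str, ref: AtomRef) -> np.ndarray:
    """Resolve a reference to a concrete position (Å) in a model.

    Among alternate locations the highest-occupancy record wins; ties go to
    altloc 'A', then lexical order.  If the reference carries a residue
    letter that disagrees with the model's residue type, resolution fails
    rather than silently measuring the wrong residue.
    """
    if chain_id not in model.chain_ids:
        raise ResolutionError(f"chain '{chain_id}' absent from model {model.model_id}")
    resname = model.residue_name_of(chain_id, ref.author_resid)
    if resname is None:
        raise ResolutionError(
            f"residue {ref.author_resid} absent from chain {chain_id} "
            f"of model {model.model_id}"
        )
    if ref.residue_letter is not None:
        letter = _one_letter(resname)
        if letter is not None and letter != ref.residue_letter:
            raise ResolutionError(
                f"residue-letter mismatch at {chain_id}:{ref.author_resid}: "
                f"reference says {ref.residue_letter}, model has {resname} ({letter})"
            )
    rows = model.atom_rows(chain_id, ref.author_resid, ref.atom_name)
    if rows.empty:
        raise ResolutionError(
            f"atom {ref.atom_name} absent on {resname} {ref.author_resid} "
            f"(chain {chain_id}, model {model.model_id})"
        )
    # altloc policy: highest occupancy, then 'A', then lexical
    rows = rows.sort_values(
        by=["occupancy", "altloc"],
        ascending=[False, True],
        key=lambda col: col if col.name == "occupancy" else col.map(
            lambda a: "" if a == "A" else a or "~"
        ),
        kind="stable",
    )
    top = rows.iloc[0]
    return np.array([top["x"], top["y"], top["z"]], dtype=float)


def range_to_tokens(
    rng: ResidueRange, bundle: ConfidenceBundle, chain_id: str
) -> list[int]:
    """Token positions (ordered by author residue number) for a residue range
    on the given chain; every residue must be covered by the token map."""
    gaps = [r for r in rng.residues() if not bundle.has_token(chain_id, r)]
    if gaps:
        raise CoverageError(
            f"residues missing from token map for chain {chain_id}: {gaps}"
        )
    return [bundle.token_index(chain_id, r) for r in rng.residues()]
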