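"""AF3-style confidence aggregation across an ensemble.

For receptor–effector complexes, prediction confidence at the interface is
summarised by (a) the mean predicted aligned error (PAE) between an effector
motif — e.g. the β-arrestin-2 finger loop (residues 64–77) or the Gαq
C-terminal helix (residues 332–359) — and a partner chain, and (b) the ipTM
score (whole-complex or per chain pair).  Because PAE is asymmetric (entry
(i, j) is the error of token j aligned on token i) the motif average is
available in both orientations and, by default, as their symmetric mean.

pLDDT is carried and summarised per model but drives no decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import CoverageError, EnsembleFPError
from .model_io import ConfidenceBundle, Ensemble
from .selection import ResidueRange, range_to_tokens

__all__ = [
    "MotifPAESpec",
    "ConfidenceSummary",
    "motif_pae",
    "get_iptm",
    "chain_pair_iptm",
    "summarize_confidence",
    "compare_ensembles",
]

ORIENTATIONS = ("motif-on-partner", "partner-on-motif", "symmetric-mean")


@dataclass(frozen=True)
class MotifPAESpec:
    """An effector-motif PAE average: motif residue range vs a partner
    (a residue range, or a whole chain role)."""

    name: str
    motif: ResidueRange
    partner: ResidueRange | str = "receptor"
    orientation: str = "symmetric-mean"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation '{self.orientation}' not one of {ORIENTATIONS}"
            )


def _chain_tokens(bundle: ConfidenceBundle, chain_id: str) -> list[int]:
    return [i for i, (c, _) in enumerate(bundle.tokens) if c == chain_id]


def _resolve_tokens(
    bundle: ConfidenceBundle,
    target: ResidueRange | str,
    roles: Mapping[str, str] | None,
) -> list[int]:
    roles = roles or {}
    if isinstance(target, ResidueRange):
        chain_id = roles.get(target.chain_role, target.chain_role)
        return range_to_tokens(target, bundle, chain_id)
    chain_id = roles.get(target, target)
    toks = _chain_tokens(bundle, chain_id)
    if not toks:
        raise CoverageError(f"no tokens found for chain '{chain_id}'")
    return toks


def motif_pae(
    bundle: ConfidenceBundle,
    spec: MotifPAESpec,
    roles: Mapping[str, str] | None = None,
    orientation: str | None = None,
) -> float:
    """Arithmetic mean of the PAE submatrix selected by the spec.

    ``motif-on-partner`` averages rows = partner tokens, columns = motif
    tokens (the error of motif positions when aligned on the partner);
    ``partner-on-motif`` is the transpose selection; ``symmetric-mean`` is
    the mean of the two oriented results.
    """
    orientation = orientation or spec.orientation
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation '{orientation}' not one of {ORIENTATIONS}")
    motif = _resolve_tokens(bundle, spec.motif, roles)
    partner = _resolve_tokens(bundle, spec.partner, roles)
    if not motif or not partner:
        raise CoverageError(f"spec '{spec.name}': empty token set")
    if set(motif) & set(partner):
        raise CoverageError(
            f"spec '{spec.name}': motif and partner token sets overlap"
        )
    # fsum gives a correctly rounded mean, independent of iteration order.
    def block_mean(rows: list[int], cols: list[int]) -> float:
        sub = bundle.pae[np.ix_(rows, cols)]
        return math.fsum(sub.ravel().tolist()) / sub.size

    if orientation == "motif-on-partner":
        return block_mean(partner, motif)
    if orientation == "partner-on-motif":
        return block_mean(motif, partner)
    return 0.5 * (block_mean(partner, motif) + block_mean(motif, partner))


def get_iptm(bundle: ConfidenceBundle) -> float:
    """The whole-complex ipTM score, unchanged from the JSON."""
    return float(bundle.iptm)


def chain_pair_iptm(
    bundle: ConfidenceBundle,
    role_a: str,
    role_b: str,
    roles: Mapping[str, str] | None = None,
) -> float:
    """The ipTM entry for an ordered chain pair (roles resolved to chain ids
    through the run configuration)."""
    if bundle.chain_pair_iptm is None:
        raise EnsembleFPError(
            "confidence bundle carries no chain_pair_iptm table"
        )
    roles = roles or {}
    key = (roles.get(role_a, role_a), roles.get(role_b, role_b))
    if key not in bundle.chain_pair_iptm:
        raise EnsembleFPError(f"chain pair {key} absent from chain_pair_iptm")
    return float(bundle.chain_pair_iptm[key])


@dataclass
class ConfidenceSummary:
    """Per-model confidence table for one ensemble plus distribution stats
    (mean, median, quartiles) per numeric column."""

    label: str
    table: pd.DataFrame
    stats: pd.DataFrame
    missing: list[str] = field(default_factory=list)


def summarize_confidence(
    ens: Ensemble,
    specs: Sequence[MotifPAESpec],
    roles: Mapping[str, str] | None = None,
) -> ConfidenceSummary:
    """Tabulate ipTM, mean pLDDT and each motif-PAE spec per model.

    For every spec the value under its configured orientation is reported
    together with both oriented values (PAE is asymmetric; transparency over
    guessing a direction).  Models without confidence bundles are listed in
    ``missing``.
    """
    rows: list[dict] = []
    missing: list[str] = []
    for model in ens.models:
        bundle = ens.confidence.get(model.model_id)
        if bundle is None:
            missing.append(model.model_id)
            continue
        row: dict = {
            "model_id": model.model_id,
            "iptm": get_iptm(bundle),
            "plddt_mean": float(np.mean(bundle.plddt)),
        }
        for spec in specs:
            row[spec.name] = motif_pae(bundle, spec, roles)
            row[f"{spec.name}_motif_on_partner"] = motif_pae(
                bundle, spec, roles, orientation="motif-on-partner"
            )
            row[f"{spec.name}_partner_on_motif"] = motif_pae(
                bundle, spec, roles, orientation="partner-on-motif"
            )
        rows.append(row)
    if not rows:
        raise EnsembleFPError(
            f"ensemble '{ens.label}' has no models with confidence attached"
        )
    table = pd.DataFrame(rows)
    numeric = table.drop(columns=["model_id"])
    stats = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "median": numeric.median(),
            "q25": numeric.quantile(0.25),
            "q75": numeric.quantile(0.75),
        }
    )
    stats.index.name = "column"
    return ConfidenceSummary(label=ens.label, table=table, stats=stats, missing=missing)


def compare_ensembles(
    a: ConfidenceSummary, b: ConfidenceSummary, column: str
) -> dict[str, float]:
    """Descriptive comparison of one confidence column between two
    ensembles: difference of means (a − b) and the common-language rank
    statistic P(X_a > X_b) (ties counted half). No significance claims."""
    for summary in (a, b):
        if column not in summary.table.columns:
            raise KeyError(f"column '{column}' absent from ensemble '{summary.label}'")
    va = a.table[column].to_numpy(dtype=float)
    vb = b.table[column].to_numpy(dtype=float)
    u = mannwhitneyu(va, vb, alternative="two-sided").statistic
    return {
        "mean_difference": float(va.mean() - vb.mean()),
        "rank_statistic": float(u / (len(va) * len(vb))),
    }
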