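"""Config-driven orchestration of the full fingerprinting analysis.

A single YAML mapping names the input ensembles, the chain-role map, the
superposition selection, the distance pairs (compact notation), the
classification axes, the 2D maps and the motif-PAE specs.  ``run`` executes
the stages in a fixed order — load, superpose, distances, maps, state calls,
representatives, confidence — and writes TSV tables plus a JSON run summary
carrying the config hash and seed, so identical config + inputs + seed give
byte-identical outputs.  All tables are collected in memory and written
together at the end; a failing stage therefore leaves no partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .confidence import MotifPAESpec, summarize_confidence
from .errors import EnsembleFPError, ParseError, ValidationError
from .geometry import (
    DEFAULT_BIN_WIDTH,
    DistancePairSpec,
    DistanceSeries,
    classify_states,
    ensemble_distances,
    histogram2d,
    select_representative,
)
from .model_io import Ensemble, EnsembleManifest, load_ensemble, write_tables
from .selection import ResidueRange, parse_atomref
from .superpose import PAR1_TM_RANGES, SuperpositionSelection, align_ensemble
from .synthetic import PAR1_PAIRS

__all__ = ["RunConfig", "RunResult", "run", "validate", "default_config"]

logger = logging.getLogger("ensemblefp")


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", text).strip("_")


@dataclass
class RunConfig:
    """Validated run configuration; see ``default_config`` for the shape."""

    raw: dict

    # ---- constructors ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} is not a mapping")
        return cls(raw=data)

    # ---- accessors -------------------------------------------------------

    @property
    def roles(self) -> dict[str, str]:
        return dict(self.raw.get("roles", {}))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("output_dir", "ensemblefp_out"))

    @property
    def rng_seed(self) -> int:
        return int(self.raw.get("rng_seed", 0))

    @property
    def bin_width(self) -> float:
        return float(self.raw.get("histogram", {}).get("bin_width", DEFAULT_BIN_WIDTH))

    @property
    def log_level(self) -> str:
        return str(self.raw.get("log_level", "INFO"))

    def pair_specs(self) -> list[DistancePairSpec]:
        specs = []
        for entry in self.raw.get("pairs", []):
            specs.append(
                DistancePairSpec.from_strings(
                    entry["a"],
                    entry["b"],
                    role_a=entry.get("role_a", "receptor"),
                    role_b=entry.get("role_b", "receptor"),
                    name=entry.get("name"),
                )
            )
        return specs

    def axes(self) -> dict[str, dict]:
        return dict(self.raw.get("axes", {}))

    def maps(self) -> list[tuple[str, str]]:
        return [tuple(m) for m in self.raw.get("histogram", {}).get("maps", [])]

    def motif_specs(self) -> list[MotifPAESpec]:
        specs = []
        for entry in self.raw.get("motif_pae", []):
            motif = entry["motif"]
            partner = entry.get("partner", "receptor")
            if isinstance(partner, Mapping):
                partner = ResidueRange(
                    partner["chain_role"], int(partner["start"]), int(partner["end"])
                )
            specs.append(
                MotifPAESpec(
                    name=entry["name"],
                    motif=ResidueRange(
                        motif["chain_role"], int(motif["start"]), int(motif["end"])
                    ),
                    partner=partner,
                    orientation=entry.get("orientation", "symmetric-mean"),
                )
            )
        return specs

    def superposition(self) -> SuperpositionSelection | None:
        sp = self.raw.get("superposition")
        if sp is None or not sp.get("enabled", True):
            return None
        return SuperpositionSelection(
            chain_role=sp.get("chain_role", "receptor"),
            ranges=tuple(tuple(r) for r in sp.get("ranges", PAR1_TM_RANGES)),
            atom_policy=sp.get("atom_policy", "ca"),
        )

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # ---- validation ------------------------------------------------------

    def diagnostics(self) -> list[str]:
        """Every violated constraint, as human-readable strings; empty when
        the config is clean.  No I/O beyond existence checks."""
        out: list[str] = []
        roles = self.roles
        ensembles = self.raw.get("ensembles", {})
        if not ensembles:
            out.append("ensembles: at least one input ensemble is required")
        for label, entry in ensembles.items():
            if not isinstance(entry, Mapping) or "directory" not in entry:
                out.append(f"ensembles.{label}: missing 'directory'")

        pair_names: set[str] = set()
        for i, entry in enumerate(self.raw.get("pairs", [])):
            for side in ("a", "b"):
                text = entry.get(side)
                if text is None:
                    out.append(f"pairs[{i}].{side}: missing atom address")
                    continue
                try:
                    parse_atomref(text)
                except ParseError as exc:
                    out.append(f"pairs[{i}].{side}: {exc}")
                role = entry.get(f"role_{side}", "receptor")
                if role not in roles:
                    out.append(f"pairs[{i}].role_{side}: undefined chain role '{role}'")
            pair_names.add(entry.get("name") or f"{entry.get('a')}-{entry.get('b')}")

        for axis, entry in self.axes().items():
            for p in entry.get("pairs", []):
                if p not in pair_names:
                    out.append(f"axes.{axis}: unknown pair '{p}'")
            labels = entry.get("labels")
            if labels is not None and len(labels) != 2:
                out.append(f"axes.{axis}: labels must be a [low, high] pair")

        hist = self.raw.get("histogram", {})
        if "bin_width" in hist and float(hist["bin_width"]) <= 0:
            out.append(f"histogram.bin_width: must be positive, got {hist['bin_width']}")
        for m in hist.get("maps", []):
            if len(m) != 2 or any(p not in pair_names for p in m):
                out.append(f"histogram.maps: invalid map entry {m}")

        cls = self.raw.get("classification", {})
        method = cls.get("method", "two-cluster")
        if method not in ("two-cluster", "fixed-threshold"):
            out.append(f"classification.method: unknown method '{method}'")
        if method == "fixed-threshold":
            cuts = cls.get("thresholds", {})
            for axis in self.axes():
                if axis not in cuts:
                    out.append(f"classification.thresholds: missing cut for axis '{axis}'")

        for i, entry in enumerate(self.raw.get("motif_pae", [])):
            if "name" not in entry or "motif" not in entry:
                out.append(f"motif_pae[{i}]: needs 'name' and 'motif'")
                continue
            motif = entry["motif"]
            if motif.get("chain_role") not in roles:
                out.append(
                    f"motif_pae[{i}]: undefined chain role '{motif.get('chain_role')}'"
                )

        sp = self.raw.get("superposition")
        if sp and sp.get("chain_role", "receptor") not in roles:
            out.append(
                f"superposition: undefined chain role '{sp.get('chain_role')}'"
            )
        return out


@dataclass
class RunResult:
    exit_status: int
    manifest: dict[str, str] = field(default_factory=dict)


def validate(config_path: str | Path) -> list[str]:
    """Load a config file and return its diagnostics (empty = clean)."""
    config = RunConfig.from_yaml(config_path)
    return config.diagnostics()


def _map_table(map2d) -> pd.DataFrame:
    cols = [f"y[{e:g}]" for e in map2d.y_edges[:-1]]
    table = pd.DataFrame(map2d.counts, columns=cols)
    table.insert(0, "x_edge_left", map2d.x_edges[:-1])
    return table


def run(config: RunConfig) -> RunResult:
    """Execute all stages on every configured ensemble and write tables."""
    diags = config.diagnostics()
    if diags:
        raise ValidationError("invalid configuration:\n" + "\n".join(diags))

    logging.basicConfig(level=config.log_level)
    roles = config.roles
    pair_specs = config.pair_specs()
    specs_by_name = {s.name: s for s in pair_specs}
    motif_specs = config.motif_specs()
    sel = config.superposition()
    cls_cfg = config.raw.get("classification", {})
    method = cls_cfg.get("method", "two-cluster")
    thresholds = cls_cfg.get("thresholds")

    tables: dict[str, pd.DataFrame] = {}
    rep_rows: list[dict] = []

    for label, entry in config.raw.get("ensembles", {}).items():
        manifest_cfg = entry.get("manifest") or {}
        ens = load_ensemble(
            entry["directory"],
            manifest=EnsembleManifest(**manifest_cfg),
            label=label,
            residue_offsets=entry.get("residue_offsets"),
        )
        logger.info("loaded ensemble '%s': %d models", label, len(ens))

        if sel is not None:
            ens = align_ensemble(ens, sel, roles=roles)
            logger.info("aligned ensemble '%s' on %s", label, sel.chain_role)

        series = ensemble_distances(ens, pair_specs, roles)
        by_name = {s.name: s for s in series}
        dist_table = pd.DataFrame(
            {
                "model_id": ens.model_ids,
                "seed": [m.seed for m in ens.models],
                "sample": [m.sample_index for m in ens.models],
                **{s.name: s.values for s in series},
            }
        )
        tables[f"distances_{_slug(label)}"] = dist_table
        for s in series:
            if s.skipped:
                logger.info("pair %s skipped models: %s", s.name, s.skipped)

        for x_name, y_name in config.maps():
            map2d = histogram2d(by_name[x_name], by_name[y_name], config.bin_width)
            tables[f"map_{_slug(label)}_{_slug(x_name)}_{_slug(y_name)}"] = _map_table(
                map2d
            )
            rep_rows.append(
                {
                    "ensemble": label,
                    "x_pair": x_name,
                    "y_pair": y_name,
                    "representative": select_representative(
                        map2d, by_name[x_name], by_name[y_name]
                    ),
                }
            )

        axes_cfg = config.axes()
        if axes_cfg:
            series_by_axis = {
                axis: [by_name[p] for p in entry_ax.get("pairs", [])]
                for axis, entry_ax in axes_cfg.items()
            }
            labels_by_axis = {
                axis: tuple(entry_ax["labels"])
                for axis, entry_ax in axes_cfg.items()
                if "labels" in entry_ax
            }
            calls = classify_states(
                series_by_axis,
                method=method,
                thresholds=thresholds,
                labels=labels_by_axis,
                random_state=config.rng_seed,
            )
            state_table = pd.DataFrame(
                [{"model_id": c.model_id, **c.states} for c in calls]
            )
            tables[f"states_{_slug(label)}"] = state_table
            logger.info(
                "state calls for '%s': %s", label, calls[0].params["per_axis"]
            )

        if ens.confidence and motif_specs:
            summary = summarize_confidence(ens, motif_specs, roles)
            tables[f"confidence_{_slug(label)}"] = summary.table
            tables[f"confidence_stats_{_slug(label)}"] = summary.stats.reset_index()
            if summary.missing:
                logger.info(
                    "'%s': %d models lack confidence", label, len(summary.missing)
                )

    if rep_rows:
        tables["representatives"] = pd.DataFrame(rep_rows)

    if not tables:
        raise EnsembleFPError("pipeline produced no tables")

    run_info = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "config": config.raw,
        "tables": sorted(tables),
    }
    manifest = write_tables(tables, config.output_dir, run_info=run_info)
    return RunResult(exit_status=0, manifest=manifest)


def default_config(
    directory: str | Path,
    output_dir: str | Path,
    label: str = "toy",
    rng_seed: int = 0,
    with_partner: bool = True,
) -> RunConfig:
    """A ready-to-run config for the synthetic preset: the eight fingerprint
    pairs, pocket/effector/interface axes and maps, and the finger-loop
    motif-PAE spec."""
    pairs = [
        {"a": a, "b": b, "role_a": ra, "role_b": rb}
        for a, b, ra, rb in (PAR1_PAIRS if with_partner else PAR1_PAIRS[:4])
    ]
    names = [f"{p['a']}-{p['b']}" for p in pairs]
    axes: dict[str, Any] = {
        "pocket": {"pairs": names[0:2], "labels": ["constricted", "open"]},
        "effector": {"pairs": names[2:4], "labels": ["narrow", "extended"]},
    }
    maps = [[names[0], names[1]], [names[2], names[3]]]
    raw: dict[str, Any] = {
        "ensembles": {label: {"directory": str(directory)}},
        "roles": {"receptor": "A", "barr2": "B"},
        "superposition": {
            "enabled": True,
            "chain_role": "receptor",
            "ranges": [list(r) for r in PAR1_TM_RANGES],
            "atom_policy": "ca",
        },
        "pairs": pairs,
        "axes": axes,
        "histogram": {"bin_width": DEFAULT_BIN_WIDTH, "maps": maps},
        "classification": {"method": "two-cluster"},
        "output_dir": str(output_dir),
        "rng_seed": rng_seed,
        "log_level": "INFO",
    }
    if with_partner:
        axes["interface"] = {
            "pairs": names[4:8],
            "labels": ["engaged", "disengaged"],
        }
        maps.append([names[6], names[4]])
        raw["motif_pae"] = [
            {
                "name": "barr2_flr_pae",
                "motif": {"chain_role": "barr2", "start": 64, "end": 77},
                "partner": "receptor",
                "orientation": "symmetric-mean",
            }
        ]
    return RunConfig(raw=raw)
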