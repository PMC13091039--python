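"""Structure/confidence reading, ensemble assembly and table writing."""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import pytest

from ensemblefp import (
    CompositionError,
    DimensionError,
    EnsembleManifest,
    ParseError,
    load_ensemble,
    read_confidence,
    read_model,
    write_tables,
)
from ensemblefp.synthetic import generate_ensemble, par1_preset

from conftest import minimal_cif


class TestReadModel:
    def test_minimal_single_atom(self, tmp_path):
        model = read_model(minimal_cif(tmp_path / "one.cif"))
        assert model.n_atoms == 1
        assert model.chain_ids == ["A"]
        rec = next(model.iter_atoms())
        assert rec.atom_name == "CA" and rec.residue_name == "ALA"
        assert np.allclose(rec.position, 0.0)
        assert rec.bfactor == pytest.approx(90.0)

    def test_atom_count_matches_file_records(self, small_dir):
        """The parsed atom count equals an independent count of coordinate
        records in the written file."""
        out, truth = small_dir
        path = sorted(out.glob("*_model.cif"))[0]
        n_records = sum(
            1 for line in path.read_text().splitlines() if line.startswith("ATOM")
        )
        model = read_model(path)
        assert model.n_atoms == n_records == truth.atom_count
        assert set(model.chain_ids) == {"A", "B"}

    def test_duplicate_atom_key_rejected(self, tmp_path):
        dup = "ATOM 2 C CA . ALA A A 1 1 1.000 0.000 0.000 1.00 90.00\n"
        with pytest.raises(ParseError, match="uniqueness"):
            read_model(minimal_cif(tmp_path / "dup.cif", lines_extra=dup))

    def test_missing_file_and_bad_content(self, tmp_path):
        with pytest.raises(ParseError):
            read_model(tmp_path / "absent.cif")
        bad = tmp_path / "empty.cif"
        bad.write_text("data_x\n# no atoms\n")
        with pytest.raises(ParseError, match="empty atom list|no models"):
            read_model(bad)

    def test_residue_offset_map(self, tmp_path):
        model = read_model(minimal_cif(tmp_path / "one.cif"), residue_offsets={"A": 10})
        assert next(model.iter_atoms()).author_resid == 11

    def test_roundtrip_coordinates_within_format_precision(self, small_spec, small_dir):
        """Written-then-reread models match generator coordinates to the
        mmCIF precision and share the (chain, resid, atom) key set."""
        from ensemblefp.synthetic import template_atoms

        out, truth = small_dir
        noiseless = par1_preset(n_seeds=1, models_per_seed=1, noise_sigma=0.0,
                                mixture_weight=1.0, rng_seed=3)
        d = out.parent / "noiseless_roundtrip"
        generate_ensemble(noiseless, d)
        model = read_model(sorted(d.glob("*_model.cif"))[0])
        expected = template_atoms(noiseless, "A")
        keys = lambda t: list(zip(t["chain_id"], t["author_resid"], t["atom_name"]))
        assert keys(model.atoms) == keys(expected)
        got = model.atoms[["x", "y", "z"]].to_numpy()
        want = expected[["x", "y", "z"]].to_numpy()
        assert np.abs(got - want).max() <= 1e-3


class TestReadConfidence:
    def _write_pair(self, tmp_path, summary: dict, full: dict):
        sp = tmp_path / "s.json"
        fp = tmp_path / "f.json"
        sp.write_text(json.dumps(summary))
        fp.write_text(json.dumps(full))
        return sp, fp

    def _four_res_model(self, tmp_path):
        lines = "".join(
            f"ATOM {i + 2} C CA . ALA A A 1 {i + 2} {float(i):.3f} 0.000 0.000 1.00 90.00\n"
            for i in range(3)
        )
        return read_model(minimal_cif(tmp_path / "m4.cif", lines_extra=lines))

    def test_constant_pae_propagates(self, tmp_path):
        model = self._four_res_model(tmp_path)
        sp, fp = self._write_pair(
            tmp_path,
            {"iptm": 0.0},
            {"pae": [[5.0] * 4] * 4, "plddt": [70.0] * 4},
        )
        bundle = read_confidence(sp, fp, model)
        assert bundle.iptm == 0.0
        assert (bundle.pae == 5.0).all()
        assert bundle.n_tokens == 4

    def test_pae_dimension_mismatch(self, tmp_path):
        model = self._four_res_model(tmp_path)
        sp, fp = self._write_pair(
            tmp_path,
            {"iptm": 0.5},
            {"pae": [[1.0] * 10] * 10, "plddt": [70.0] * 10},
        )
        with pytest.raises(DimensionError, match="does not match"):
            read_confidence(sp, fp, model)

    def test_missing_iptm_lists_absent_keys(self, tmp_path):
        model = self._four_res_model(tmp_path)
        sp, fp = self._write_pair(
            tmp_path, {"ptm": 0.5}, {"pae": [[1.0] * 4] * 4, "plddt": [70.0] * 4}
        )
        with pytest.raises(ParseError, match="iptm"):
            read_confidence(sp, fp, model)

    def test_pae_stored_unmodified(self, small_dir):
        """Every stored PAE entry equals the value obtained from the JSON
        text by an independent scan — no symmetrization or rescaling."""
        out, _ = small_dir
        full = sorted(out.glob("*_full_data.json"))[0]
        summary = Path(str(full).replace("_full_data", "_summary_confidences"))
        cif = Path(str(full).replace("_full_data.json", "_model.cif"))
        model = read_model(cif)
        bundle = read_confidence(summary, full, model)
        independent = np.array(json.loads(full.read_text())["pae"], dtype=float)
        assert np.array_equal(bundle.pae, independent)

    def test_token_map_matches_cumulative_offsets(self, small_spec, small_ensemble):
        """Token position of (B, 66) equals chain-A token count plus the
        within-chain rank of residue 66, computed from the generator spec."""
        ens, _ = small_ensemble
        bundle = ens.confidence[ens.model_ids[0]]
        chain_a = sum(
            seg.end - seg.start + 1 for seg in small_spec.segments if seg.chain == "A"
        )
        b_start = min(seg.start for seg in small_spec.segments if seg.chain == "B")
        assert bundle.token_index("B", 66) == chain_a + (66 - b_start)


class TestLoadEnsemble:
    def test_seed_batches_load_in_order(self, toy_ensemble):
        ens, _ = toy_ensemble
        assert len(ens) == 100
        order = [(m.seed, m.sample_index) for m in ens.models]
        assert order == sorted(order)
        assert len(set(ens.model_ids)) == 100

    def test_single_model_directory(self, tmp_path, small_dir):
        out, _ = small_dir
        lone = tmp_path / "one"
        lone.mkdir()
        src = sorted(out.glob("seed-000_sample-0*"))
        for f in src:
            (lone / f.name).write_bytes(f.read_bytes())
        ens = load_ensemble(lone)
        assert len(ens) == 1
        assert ens.confidence  # confidence attached when files present

    def test_no_matching_files(self, tmp_path):
        (tmp_path / "readme.txt").write_text("nothing here")
        with pytest.raises(CompositionError, match="no files"):
            load_ensemble(tmp_path)

    def test_inconsistent_chain_composition(self, tmp_path, small_dir):
        out, _ = small_dir
        broken = tmp_path / "broken"
        broken.mkdir()
        for f in sorted(out.glob("*_model.cif"))[:2]:
            (broken / f.name).write_bytes(f.read_bytes())
        # strip chain B from one model
        victim = sorted(broken.glob("*_model.cif"))[1]
        st = gemmi.read_structure(str(victim))
        st.setup_entities()
        model = st[0]
        for i in range(len(model) - 1, -1, -1):
            if model[i].name == "B":
                del model[i]
        victim.write_text(st.make_mmcif_document().as_string())
        with pytest.raises(CompositionError, match="chain set"):
            load_ensemble(broken)

    def test_stable_across_repeated_loads(self, small_dir):
        out, _ = small_dir
        first = load_ensemble(out)
        second = load_ensemble(out)
        assert first.model_ids == second.model_ids


class TestWriteTables:
    def test_row_counts_and_manifest(self, tmp_path):
        table = pd.DataFrame({"model_id": ["a", "b", "c"], "d": [1.0, 2.0, 3.0]})
        manifest = write_tables({"distances": table}, tmp_path, run_info={"rng_seed": 0})
        text = Path(manifest["distances"]).read_text().splitlines()
        assert len(text) == 4  # header + 3 rows
        assert "run_summary" in manifest

    def test_long_format_keyed_by_label(self, tmp_path):
        long = pd.concat(
            [
                pd.DataFrame({"ensemble": "x", "iptm": [0.1, 0.2]}),
                pd.DataFrame({"ensemble": "y", "iptm": [0.3]}),
            ]
        )
        manifest = write_tables({"confidence": long}, tmp_path)
        back = pd.read_csv(manifest["confidence"], sep="\t")
        assert back["ensemble"].tolist() == ["x", "x", "y"]

    def test_empty_results_write_nothing(self, tmp_path):
        with pytest.raises(ValueError):
            write_tables({}, tmp_path / "out")
        assert not (tmp_path / "out").exists()

    def test_rerun_overwrites(self, tmp_path):
        t1 = pd.DataFrame({"v": [1]})
        t2 = pd.DataFrame({"v": [2]})
        write_tables({"t": t1}, tmp_path)
        write_tables({"t": t2}, tmp_path)
        assert pd.read_csv(tmp_path / "t.tsv", sep="\t")["v"].tolist() == [2]
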