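"""End-to-end pipeline runs from a declarative config.

The config is INI-style: flat key-value entries grouped in sections, one
section per stage plus a ``[run]`` section carrying the global seed,
stage list and output directory.  Stages execute in the order listed;
any failure aborts the run naming the stage, with earlier outputs
preserved.  Every run writes ``report.json`` (all fitted parameters and
statistics) and ``run.log`` (package version, seed, input file hashes).

Example::

    [run]
    stages = simulate_titration, fit_binding
    seed = 7
    outdir = out

    [simulate_titration]
    kd_uM = 380
    delta_max = T39:0.8,L40:0.6
    noise_sd_ppm = 0.005

    [fit_binding]
    residues = T39,L40
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, binding, composition, ensemble as ens, io, scattering, shifts, synth


@dataclass
class RunConfig:
    stages: list[str]
    seed: int
    outdir: Path
    params: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        if "run" not in cp:
            raise ValueError("config needs a [run] section")
        run = cp["run"]
        stages = [s.strip() for s in run.get("stages", "").split(",") if s.strip()]
        if not stages:
            raise ValueError("[run] stages is empty")
        cfg = cls(
            stages=stages,
            seed=run.getint("seed", 0),
            outdir=Path(run.get("outdir", "idpkit_out")),
            params={s: dict(cp[s]) for s in cp.sections() if s != "run"},
        )
        return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _parse_res_map(text: str) -> dict[str, float]:
    out = {}
    for item in text.split(","):
        key, val = item.split(":")
        out[key.strip()] = float(val)
    return out


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the report dict.

    The report is also written to ``<outdir>/report.json`` and a run log
    with version, seed and input hashes to ``<outdir>/run.log``.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    log_lines = [f"idpkit {__version__}", f"seed {config.seed}"]
    state: dict = {}

    for stage in config.stages:
        p = config.params.get(stage, {})
        try:
            out = _run_stage(stage, p, config, state, log_lines)
        except Exception as exc:  # abort but keep partial outputs
            report["stages"][stage] = {"error": str(exc)}
            _write_report(config, report, log_lines)
            raise PipelineError(stage, exc) from exc
        report["stages"][stage] = out
    _write_report(config, report, log_lines)
    return report


def _write_report(config: RunConfig, report: dict, log_lines: list[str]) -> None:
    (config.outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (config.outdir / "run.log").write_text("\n".join(log_lines) + "\n")


def _run_stage(stage, p, config, state, log_lines) -> dict:
    seed = int(p.get("seed", config.seed))
    log_lines.append(f"stage {stage} seed={seed}")
    for key, val in p.items():
        if key.endswith(("_file", "_fasta", "_pdb", "_csv", "_dat")):
            f = Path(val)
            if not f.exists():
                raise FileNotFoundError(f"input {f} for stage {stage} does not exist")
            log_lines.append(f"  input {f} sha256:{_hash_file(f)}")

    if stage == "simulate_sequences":
        fq = synth.uniform_aa_frequencies(
            **{k[5:].upper(): float(v) for k, v in p.items() if k.startswith("freq_")}
        )
        fb = synth.uniform_aa_frequencies()
        n = int(p.get("n_seqs", 500))
        query, bg = synth.gen_sequence_sets(fq, fb, n_seqs=n, seed=seed)
        io.write_fasta(query, config.outdir / "query.fasta")
        io.write_fasta(bg, config.outdir / "background.fasta")
        state["sequences"] = (query, bg)
        return {"n_query": len(query), "n_background": len(bg)}

    if stage == "compose":
        if "query_fasta" in p:
            query = io.read_fasta(p["query_fasta"])
            bg = io.read_fasta(p["background_fasta"])
        else:
            query, bg = state["sequences"]
        prof = composition.enrichment_profile(
            query, bg,
            n_boot=int(p.get("n_boot", 50000)),
            alpha=float(p.get("alpha", 0.05)),
            seed=seed,
        )
        prof.to_csv(config.outdir / "enrichment.csv")
        return {
            "significant": prof.index[prof["significant"]].tolist(),
            "enrichment_E": float(prof.loc["E", "enrichment"]),
            "enrichment_D": float(prof.loc["D", "enrichment"]),
        }

    if stage == "simulate_titration":
        truth = synth.TitrationGroundTruth(
            K_D=float(p.get("kd_um", 380.0)),
            delta_max=_parse_res_map(p.get("delta_max", "T39:0.8,L40:0.6")),
            P0=float(p.get("p0_um", 50.0)),
            noise_sd=float(p.get("noise_sd_ppm", 0.0)),
            seed=seed,
        )
        series = synth.gen_titration(truth)
        io.write_titration(series, config.outdir / "titration_ref.csv")
        state["titration_ref"] = series
        state["titration_truth"] = truth
        if "kd_variant_um" in p:
            vt = synth.TitrationGroundTruth(
                K_D=float(p["kd_variant_um"]),
                delta_max=truth.delta_max, P0=truth.P0,
                noise_sd=truth.noise_sd, seed=seed + 1,
            )
            var = synth.gen_titration(vt)
            io.write_titration(var, config.outdir / "titration_var.csv")
            state["titration_var"] = var
        return {"kd_true_uM": truth.K_D}

    if stage == "fit_binding":
        series = state.get("titration_ref")
        if series is None:
            series = io.read_titration(p["reference_csv"], float(p.get("p0_um", 50.0)))
        residues = [r.strip() for r in p.get("residues", "T39,L40").split(",")]
        ref = binding.fit_reference(series, residues)
        out = {
            "K_D_uM": ref.K_D, "K_D_stderr": ref.K_D_stderr,
            "delta_max_ppm": ref.delta_max,
        }
        var = state.get("titration_var")
        if var is None and "variant_csv" in p:
            var = io.read_titration(p["variant_csv"], float(p.get("p0_um", 50.0)))
        if var is not None:
            rel = binding.fit_relative(var, ref, residues)
            out["variant_K_D_uM"] = rel.K_D
            out["fold_change"] = rel.fold_change
        return out

    if stage == "simulate_ensemble":
        model = synth.HelixModel(
            n_residues=int(p.get("n_residues", 30)),
            helix_region=(int(p.get("helix_first", 8)), int(p.get("helix_last", 23))),
            p_nucleate=float(p.get("p_nucleate", 0.1)),
            p_stay=float(p.get("p_stay", 0.9)),
            seed=seed,
        )
        ensemble = synth.gen_ensemble(model, n_frames=int(p.get("n_frames", 100)))
        bias = synth.gen_bias(ensemble)
        ensemble.bias = bias
        io.write_ensemble(ensemble, config.outdir / "ensemble.pdb")
        io.write_bias(bias, config.outdir / "bias.csv")
        state["ensemble"] = ensemble
        return {
            "n_frames": ensemble.n_frames,
            "true_mean_helicity": float(ensemble.helix_truth.mean()),
        }

    if stage == "ensemble_analysis":
        ensemble = state.get("ensemble")
        if ensemble is None:
            ensemble = io.read_ensemble(p["ensemble_pdb"], p.get("bias_csv"))
        rg = ens.ensemble_rg(ensemble)
        w = ensemble.weights
        rg_err, _, _ = ens.block_average_error(rg, w)
        census = ens.helix_census(ensemble)
        cmap = ens.contact_map(ensemble, cutoff=float(p.get("cutoff", 8.5)),
                               stride=int(p.get("stride", 10)))
        np.savetxt(config.outdir / "contact_map.csv", cmap, delimiter=",")
        np.savetxt(config.outdir / "helix_census.csv", census, delimiter=",")
        return {
            "mean_rg_nm": ens.weighted_mean(rg, w),
            "rg_block_error_nm": rg_err,
            "mean_helicity": float(census.mean()),
        }

    if stage == "simulate_scattering":
        curve = synth.gen_scattering(
            Rg_true=float(p.get("rg_nm", 2.0)),
            noise_frac=float(p.get("noise_frac", 0.0)),
            seed=seed,
        )
        io.write_scattering(curve, config.outdir / "saxs.dat")
        state["saxs"] = curve
        return {"rg_true_nm": float(p.get("rg_nm", 2.0))}

    if stage == "guinier":
        curve = state.get("saxs")
        if curve is None:
            curve = io.read_scattering(p["saxs_dat"])
        fit = scattering.guinier_fit(curve, target=float(p.get("target", 0.9)))
        return {
            "Rg_nm": fit.Rg, "I0": fit.I0,
            "q_max_used": fit.q_max_used, "n_points": fit.n_points_used,
        }

    raise ValueError(f"unknown stage {stage!r}")
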