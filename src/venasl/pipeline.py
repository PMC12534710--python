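"""End-to-end synthetic pipeline: simulate -> quantify -> cohort statistics.

A single structured configuration drives all stages; every source of
randomness derives from one root seed through named substreams, so a fixed
configuration reproduces every numeric output bit-identically on one
platform.  The pipeline writes a manifest recording inputs, seeds, package
version, and SHA-256 checksums of every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asl import (
    compute_do2,
    extract_adjacent_signals,
    extract_vhs,
    framewise_displacement,
    quantify_single_pld,
    subtract_average,
)
from .kinetics import AcquisitionTiming, BloodProperties, KineticConstants
from .pc import VesselROI, combine_ica, phase_to_velocity, vessel_flow
from .stats import corr_matrix, descriptive_table, ols, pairwise_adjusted, stepwise_ols
from .synthetic import (
    HEMODYNAMIC_VARIABLES,
    CohortGenParams,
    PhantomSpec,
    make_phantom,
    simulate_asl,
    simulate_cohort,
    simulate_pc,
    simulate_trust,
)
from .trust import fit_trust

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the full synthetic pipeline.

    Round-trips losslessly through YAML (``to_yaml``/``from_yaml``); every
    threshold has a default.
    """

    out_dir: str = "venasl_out"
    seed: int = 0
    n_subjects: int = 36
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    slab_width: int = 12
    venous_amplitude: float = 97.6
    yv_true: float = 0.62
    hct: float = 0.42
    ya: float = 0.98
    p_enter: float = 0.05
    p_remove: float = 0.10
    beta_shunt_vhs: float = 25.0
    beta_shunt_oef: float = 0.06
    asl_path: str | None = None  # optional measured single-delay series (NIfTI)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def _substream(root_seed: int, name: str) -> int:
    """Stable named substream seed below 2**31 derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> quantify -> cohort-stats and write a results bundle.

    Stages, in dependency order:

    1. *imaging exemplar*: one phantom subject is simulated (single-delay
       pCASL, TRUST, phase contrast), quantified, and the venous/adjacent
       slab signals extracted — a per-subject worked example of every
       quantifier;
    2. *cohort*: a synthetic cohort is drawn and the full statistics
       battery (descriptives, correlation matrix, pairwise-adjusted models,
       stepwise model of OEF) is written as CSV tables plus a JSON bundle.

    Returns the results dictionary; a manifest with seeds and checksums is
    written alongside the outputs.  Missing configured inputs fail fast
    with the offending stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the output location is implied by where the bundle lives; leaving it
    # out keeps the written bundle identical across target directories
    cfg_record = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    results: dict = {"config": cfg_record, "version": __version__}

    if config.asl_path is not None and not Path(config.asl_path).exists():
        raise FileNotFoundError(
            f"stage 'quantify-asl': configured ASL series not found: {config.asl_path}"
        )

    blood = BloodProperties(hct=config.hct, ya=config.ya)
    consts = KineticConstants()

    # --- stage 1: imaging exemplar -------------------------------------
    spec = PhantomSpec(
        grid_shape=config.grid_shape, seed=_substream(config.seed, "phantom")
    )
    masks, truth = make_phantom(spec)
    truth.venous_amplitude = config.venous_amplitude
    timing = AcquisitionTiming(plds=(1.2,), n_pairs=8)
    series = simulate_asl(
        truth,
        timing,
        blood=blood,
        consts=consts,
        noise_sd=0.0,
        seed=_substream(config.seed, "asl"),
    )
    delta = subtract_average(series)[1.2]
    cbf_map, _ = quantify_single_pld(delta, series.m0, timing, blood, consts)
    vhs = extract_vhs(cbf_map, masks["venous_sinus"], config.slab_width)
    adjacent = extract_adjacent_signals(
        cbf_map,
        {"gm": masks["GM"], "csf": masks["CSF"], "bone": masks["bone"]},
        sinus_mask=masks["venous_sinus"],
        slab_width=config.slab_width,
    )
    gm_cbf = float(np.nanmean(cbf_map[masks["GM"]]))
    zero_motion = np.zeros((2 * timing.n_pairs, 6))
    _, mean_fd = framewise_displacement(zero_motion)

    tm = simulate_trust(
        config.yv_true, hct=config.hct, seed=_substream(config.seed, "trust")
    )
    tfit = fit_trust(tm, hct=config.hct, ya=config.ya)

    rois = [
        VesselROI("ICA_left", ((10, 10), (16, 10), (16, 16), (10, 16))),
        VesselROI("ICA_right", ((40, 10), (46, 10), (46, 16), (40, 16))),
        VesselROI("SSS", ((26, 40), (34, 40), (34, 46), (26, 46))),
    ]
    velocities = {"ICA_left": 20.0, "ICA_right": 21.0, "SSS": 18.0}
    phase, _mag = simulate_pc(
        rois, velocities, seed=_substream(config.seed, "pc")
    )
    vel_img = phase_to_velocity(phase, 40.0)
    metrics = {roi.name: vessel_flow(roi, vel_img) for roi in rois}
    ica = combine_ica(metrics["ICA_left"], metrics["ICA_right"])

    results["exemplar"] = {
        "vhs": vhs,
        "adjacent_signals": adjacent,
        "gm_cbf": gm_cbf,
        "do2_single": compute_do2(gm_cbf, blood),
        "mean_fd": mean_fd,
        "trust": {
            "t2_blood": tfit.t2_blood,
            "yv": tfit.yv,
            "oef": tfit.oef,
        },
        "pc": {
            name: {"area": m.area, "velocity": m.mean_velocity, "flow": m.flow}
            for name, m in {**metrics, "ICA": ica}.items()
        },
    }

    # --- stage 2: cohort + statistics ----------------------------------
    params = CohortGenParams(
        n_subjects=config.n_subjects,
        beta_shunt_vhs=config.beta_shunt_vhs,
        beta_shunt_oef=config.beta_shunt_oef,
        seed=_substream(config.seed, "cohort"),
    )
    cohort, truth_tbl = simulate_cohort(params)
    cohort.to_csv(out / "cohort.csv", index=False)
    truth_tbl.to_csv(out / "cohort_truth.csv", index=False)

    desc = descriptive_table(cohort, continuous=list(HEMODYNAMIC_VARIABLES))
    desc.to_csv(out / "table1_descriptives.csv", index=False)

    cm = corr_matrix(cohort, HEMODYNAMIC_VARIABLES)
    cm.r.to_csv(out / "correlation_r.csv")
    cm.p.to_csv(out / "correlation_p.csv")
    cm.p_bonferroni.to_csv(out / "correlation_p_bonferroni.csv")
    _render_heatmap(cm, out / "correlation_heatmap.png")

    pw_vars = [v for v in HEMODYNAMIC_VARIABLES if v != "oef"]
    pw = pairwise_adjusted(cohort, "oef", pw_vars)
    pw.to_csv(out / "pairwise_adjusted_p.csv")

    uni = ols(cohort["oef"], cohort[["vhs"]])
    step_res, step_trace = stepwise_ols(
        cohort["oef"],
        cohort[pw_vars + ["mean_fd", "gm_signal", "csf_signal", "bone_signal"]],
        p_enter=config.p_enter,
        p_remove=config.p_remove,
    )
    step_res.to_frame().to_csv(out / "table3_stepwise.csv", index=False)

    results["cohort_stats"] = {
        "n_correlation_tests": cm.n_tests,
        "univariate_vhs_oef": {
            "slope": float(uni.estimates[1]),
            "p": float(uni.p_values[1]),
            "r2": uni.r2,
        },
        "stepwise_terms": step_res.terms,
        "stepwise_estimates": [float(v) for v in step_res.estimates],
        "stepwise_trace": [
            {"step": t.step, "action": t.action, "term": t.term, "p": t.p_value}
            for t in step_trace
        ],
    }

    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))

    manifest = {
        "version": __version__,
        "root_seed": config.seed,
        "substreams": {
            name: _substream(config.seed, name)
            for name in ("phantom", "asl", "trust", "pc", "cohort")
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _render_heatmap(cm, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cm.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm.variables)), cm.variables, rotation=90)
    ax.set_yticks(range(len(cm.variables)), cm.variables)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
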