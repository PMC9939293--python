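"""End-to-end orchestration: preprocess -> classify -> connect -> ensembles
-> population metrics, with deterministic seeding throughout."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, ensembles, popmetrics, responses, traces
from .config import PipelineConfig
from .responses import classify_active_plasticity, compute_auc, plasticity_windows
from .synthdata import Recording

__all__ = ["PipelineResult", "run_pipeline", "plasticity_session_summary"]


@dataclass
class PipelineResult:
    """Outputs of one multi-stimulus session analysis."""

    traces: traces.ActivityTraces
    classification: dict[str, pd.DataFrame]  # per stimulus
    auc: pd.DataFrame  # neurons x stimuli trial-averaged AUC
    graph: connectivity.FunctionalGraph
    ensemble_set: ensembles.EnsembleSet
    sparseness: dict[str, float]
    tuning: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Emit delimited tables and a JSON summary under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.auc.to_csv(outdir / "auc.csv", index_label="neuron")
        for stim, df in self.classification.items():
            df.to_csv(outdir / f"classification_{stim}.csv", index_label="neuron")
        edges = pd.DataFrame(sorted(self.graph.edges), columns=["a", "b"])
        edges.to_csv(outdir / "edges.csv", index=False)
        pd.DataFrame(
            {"degree": self.graph.degrees}
        ).to_csv(outdir / "degrees.csv", index_label="neuron")
        pd.DataFrame(self.ensemble_set.membership).to_csv(
            outdir / "ensemble_membership.csv", index_label="neuron"
        )
        self.tuning.to_csv(outdir / "tuning.csv", index_label="neuron")
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=2, sort_keys=True))


def run_pipeline(recording: Recording, config: PipelineConfig | None = None) -> PipelineResult:
    """Analyze one multi-stimulus session.

    Every stage logs its thresholds into the result summary; all surrogate
    randomness derives from ``config.seed`` with fixed per-stage offsets.
    """
    config = config or PipelineConfig()
    act = traces.preprocess(recording, mode="multistim",
                            neuropil_coeff=config.neuropil_coeff)
    kept = np.flatnonzero(act.kept)
    schedule = recording.schedule
    stimuli = schedule.stimulus_labels()

    classification: dict[str, pd.DataFrame] = {}
    auc_cols: dict[str, np.ndarray] = {}
    grating_stims = []
    for stim in stimuli:
        ta = responses.trial_average(act.dff, schedule, stim,
                                     baseline_s=config.stimulus_window_s)
        classification[stim] = responses.classify_active(
            ta, mode="high", high_threshold=config.high_threshold,
            alpha=config.alpha,
        )
        auc_cols[stim] = responses.compute_auc(ta.trace, schedule.dt)
        if stim.startswith("grating"):
            grating_stims.append(stim)
    auc = pd.DataFrame(auc_cols)

    graph = connectivity.build_graph(
        act.binary[kept], n_shifts=config.n_shifts,
        percentile=config.surrogate_percentile, seed=config.seed,
    )
    ens = ensembles.detect_ensembles(
        act.binary[kept], min_coactive=config.min_coactive,
        min_similarity=config.jaccard_threshold,
        n_surrogates=config.n_shifts, percentile=config.surrogate_percentile,
        seed=config.seed + 1,
    )

    sparseness = {
        stim: popmetrics.population_sparseness(auc[stim].to_numpy())
        for stim in stimuli
    }

    angles = [int(s.split("_")[1]) for s in grating_stims]
    tuning_rows = []
    for i in range(recording.n_neurons):
        resp = auc.loc[i, grating_stims].to_numpy(dtype=float)
        try:
            fit = popmetrics.fit_von_mises(resp, angles_deg=angles,
                                           r2_threshold=config.r2_threshold)
            tuning_rows.append(
                dict(theta=fit.theta, K=fit.K, A=fit.A, b=fit.b, r2=fit.r2,
                     valid=fit.valid, fwhm=fit.fwhm)
            )
        except ValueError:
            tuning_rows.append(dict(theta=np.nan, K=np.nan, A=np.nan, b=np.nan,
                                    r2=np.nan, valid=False, fwhm=np.nan))
    tuning = pd.DataFrame(tuning_rows)

    active = np.column_stack([classification[s]["active"].to_numpy() for s in stimuli])
    summary = {
        "config": config.to_dict(),
        "n_neurons": int(recording.n_neurons),
        "n_kept": int(kept.size),
        "active_fraction": responses.active_fraction(active),
        "n_edges": len(graph.edges),
        "degree_skewness": (
            float(graph.skewness) if np.var(graph.degrees) > 0 else None
        ),
        "n_ensembles": int(ens.n_ensembles),
        "ensemble_category_fractions": ensembles.ensembles_per_neuron(
            ens.membership
        )["fractions"],
        "sparseness": sparseness,
        "valid_tuning_fraction": float(tuning["valid"].mean()),
    }
    return PipelineResult(
        traces=act, classification=classification, auc=auc, graph=graph,
        ensemble_set=ens, sparseness=sparseness, tuning=tuning, summary=summary,
    )


def plasticity_session_summary(
    recording: Recording,
    config: PipelineConfig | None = None,
    with_graph: bool = True,
) -> dict:
    """Summary statistics of one single-stimulus plasticity session.

    Returns the quantities whose post/pre-training ratios measure
    plasticity: mean population AUC over the first 10 s of stimulus, active
    and high-responder fractions, mean node degree of active neurons, and
    the overlap-decay rate tau.
    """
    config = config or PipelineConfig()
    act = traces.preprocess(recording, mode="plasticity",
                            neuropil_coeff=config.neuropil_coeff)
    kept = np.flatnonzero(act.kept)
    schedule = recording.schedule
    stim_fr, _ = plasticity_windows(schedule, config.plasticity_window_s)
    cls = classify_active_plasticity(
        act, window_s=config.plasticity_window_s,
        high_threshold=config.high_threshold, alpha=config.alpha,
    )
    window_dff = act.dff[kept][:, stim_fr]
    auc = compute_auc(window_dff, schedule.dt)
    out = {
        "auc": float(np.mean(auc)) if kept.size else float("nan"),
        "active_fraction": float(cls["active"][act.kept].mean()) if kept.size else float("nan"),
        "high_responder_fraction": responses.response_fractions(
            window_dff, (config.high_responder_threshold,)
        )[config.high_responder_threshold] if kept.size else float("nan"),
        "n_kept": int(kept.size),
    }
    if with_graph and kept.size >= 2:
        graph = connectivity.build_graph(
            act.binary[kept], n_shifts=config.n_shifts,
            percentile=config.surrogate_percentile, seed=config.seed,
            frames=stim_fr,
        )
        active_kept = cls["active"].to_numpy()[kept]
        deg = graph.degrees
        out["mean_degree"] = float(deg[active_kept].mean()) if active_kept.any() else float("nan")
    max_lag = config.max_lag
    if stim_fr.max() + max_lag < schedule.n_frames and kept.size:
        curve = popmetrics.neural_overlap(
            act.dff[kept], stim_fr, max_lag=max_lag, dt=schedule.dt
        )
        tau, b = popmetrics.fit_overlap_decay(curve)
        out["tau"] = tau
        out["overlap_asymptote"] = b
    return out
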