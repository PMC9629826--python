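"""End-to-end orchestration of the synthetic dark-exposure experiment.

Simulates a four-session experiment (Baseline 1, Baseline 2, post-dark-
exposure, Recovery), bounding three conditions -- control (B1->B2),
dark exposure (B2->pDE), and light reintroduction (pDE->Rec) -- then
runs the full analysis chain: trial filtering, ANOVA responsivity,
single-trial tuning fits with permutation screening, stability deltas,
signal-correlation similarity, reliability, set-based KNN decoding, and
fixed-classifier drift, with rank-sum condition contrasts under
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decoding, io, popmetrics, preprocess, stats, synthgen, tuning
from .grid import StimulusGrid, default_grid
from .synthgen import SessionSpec

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "stage_seed"]

SESSION_NAMES = ("B1", "B2", "pDE", "Rec")
CONDITIONS = {"control": ("B1", "B2"), "DE": ("B2", "pDE"),
              "LRx": ("pDE", "Rec")}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed from the master seed.

    Stable across runs and platforms: the stage name enters through its
    CRC32, so each pipeline stage is independently reproducible.
    """
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ExperimentConfig:
    """Configuration of the synthetic experiment and its analysis.

    ``schedule`` holds one mapping per session with the SessionSpec
    fields; the default emulates the study design: a control interval
    with ongoing preference drift, a dark-exposure interval with
    reduced drift and reduced reliability, and a recovery session that
    rebounds to the baseline representation.
    """

    n_orientations: int = 12
    ori_step: float = 15.0
    sf_min: float = 0.02
    sf_max: float = 0.30
    sf_step: float = 0.02
    n_neurons: int = 60
    tuned_fraction: float = 0.4
    amplitude_mean: float = 60.0
    baseline_mean: float = 0.5
    reliability_mean: float = 0.7
    n_trials: int = 30
    locomotion_rate: float = 0.10
    blink_rate: float = 0.05
    n_baseline: int = 100
    variance_inflation: float = 1.0
    schedule: list = field(default_factory=lambda: [
        {"name": "B1"},
        {"name": "B2", "ori_jitter_deg": 10.0, "sf_jitter": 0.01},
        {"name": "pDE", "ori_jitter_deg": 3.0, "sf_jitter": 0.005,
         "reliability_multiplier": 0.6},
        {"name": "Rec", "rebound": True},
    ])
    alpha: float = 0.01
    n_perm: int = 200
    perm_percentile: float = 95.0
    fit_max_nfev: int = 100
    k: int = 4
    reliability_n_sd: float = 2.0
    bw_mode: str = "as-printed"
    seed: int = 0

    def grid(self) -> StimulusGrid:
        ori = np.arange(self.n_orientations) * self.ori_step
        n_sf = int(round((self.sf_max - self.sf_min) / self.sf_step)) + 1
        sf = np.round(self.sf_min + np.arange(n_sf) * self.sf_step, 10)
        return StimulusGrid(orientations=ori, spatial_freqs=sf)

    def session_specs(self) -> list[SessionSpec]:
        return [SessionSpec(**spec) for spec in self.schedule]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def run_experiment(config: ExperimentConfig, out_dir=None,
                   seed: int | None = None) -> dict:
    """Run the full synthetic experiment and analysis chain.

    Returns the results dictionary; with ``out_dir`` also writes
    ``results.json``, ``report.md`` and ``tables/*.csv``.
    """
    master = config.seed if seed is None else int(seed)
    specs = config.session_specs()
    names = [s.name for s in specs]
    timings: dict[str, float] = {}

    def timed(stage):
        t0 = time.perf_counter()

        def done():
            timings[stage] = round(time.perf_counter() - t0, 3)
            logger.info("stage %-12s %6.2f s", stage, timings[stage])
        return done

    done = timed("simulate")
    grid = config.grid()
    truth = synthgen.random_population(
        grid, config.n_neurons, tuned_fraction=config.tuned_fraction,
        amplitude_mean=config.amplitude_mean,
        baseline_mean=config.baseline_mean,
        reliability_mean=config.reliability_mean,
        seed=stage_seed(master, "population"))
    sessions, truths = synthgen.generate_experiment(
        grid, truth, specs, config.n_trials,
        stage_seed(master, "sessions"),
        locomotion_rate=config.locomotion_rate,
        blink_rate=config.blink_rate, n_baseline=config.n_baseline,
        variance_inflation=config.variance_inflation)
    done()

    done = timed("preprocess")
    filtered = {}
    responsive = {}
    for name, sess in zip(names, sessions):
        f = preprocess.filter_trials(sess)
        filtered[name] = f
        responsive[name] = preprocess.test_responsiveness(f, config.alpha)
    done()

    done = timed("tuning")
    fits = {}
    for name in names:
        sess = filtered[name]
        idx = np.flatnonzero(responsive[name].responsive)
        fits[name] = tuning.fit_session(
            sess, idx, n_perm=config.n_perm,
            seed=stage_seed(master, f"tuning-{name}"),
            max_nfev=config.fit_max_nfev)
        for f in fits[name].values():
            f.bw_mode = config.bw_mode
    done()

    done = timed("stability")
    deltas = {cond: tuning.stability_deltas(fits[a], fits[b])
              for cond, (a, b) in CONDITIONS.items() if a in fits and b in fits}
    done()

    done = timed("similarity")
    similarity = {}
    for cond, (a, b) in CONDITIONS.items():
        tuned_ids = sorted(
            {nid for nid, f in fits[a].items() if f.tuned} &
            {nid for nid, f in fits[b].items() if f.tuned})
        if len(tuned_ids) < 3:
            similarity[cond] = None
            continue
        mats = []
        for name in (a, b):
            sess = filtered[name]
            id_to_idx = {int(n): i for i, n in enumerate(sess.neuron_ids)}
            mats.append(popmetrics.signal_correlation(
                sess, [id_to_idx[n] for n in tuned_ids]))
        similarity[cond] = popmetrics.similarity(*mats)
    done()

    done = timed("reliability")
    rel = {name: popmetrics.reliability(filtered[name], fits[name],
                                        n_sd=config.reliability_n_sd)
           for name in names}
    done()

    done = timed("decoding")
    match_names = names[1:] if len(names) >= 3 else names
    matched = decoding.subsample_match(
        [filtered[n] for n in match_names],
        seed=stage_seed(master, "match"))
    accuracy = {}
    for name, sess in zip(match_names, matched):
        res = decoding.knn_decode(sess, k=config.k,
                                  seed=stage_seed(master, f"decode-{name}"))
        accuracy[name] = {"accuracy": res.accuracy, "chance": res.chance,
                          "n_neurons": sess.n_neurons,
                          "n_sets": int(res.confusion[0].sum())}
    done()

    done = timed("drift")
    drift_pairs = [("control", "B1", "B2"), ("DE", "B2", "pDE"),
                   ("rebound", "Rec", "pDE")]
    drift = {}
    for cond, tr, te in drift_pairs:
        if tr not in filtered or te not in filtered:
            continue
        d = decoding.fixed_classifier_drift(
            filtered[tr], filtered[te], k=config.k,
            seed=stage_seed(master, f"drift-{cond}"))
        drift[cond] = {"acc_x1": d.acc_x1, "acc_x2": d.acc_x2,
                       "drift": d.drift}
    done()

    done = timed("stats")
    contrasts = []
    if "control" in deltas and "DE" in deltas and \
            len(deltas["control"]) >= 2 and len(deltas["DE"]) >= 2:
        feats = ["d_mu_theta", "d_bw_theta", "d_mu_sf", "d_bw_sf"]
        pvals = []
        for feat in feats:
            c = stats.contrast(deltas["control"][feat].to_numpy(),
                               deltas["DE"][feat].to_numpy(), "rank-sum")
            contrasts.append({"analysis": f"stability:{feat}",
                              "condition_A": "control", "condition_B": "DE",
                              "test": c.test, "statistic": c.statistic,
                              "n": [c.n1, c.n2], "p": c.pvalue})
            pvals.append(c.pvalue)
        for row, adj in zip(contrasts[-4:], stats.bh_adjust(pvals)):
            row["p_adj"] = float(adj)
    if rel["B2"].values.size >= 2 and rel["pDE"].values.size >= 2:
        fam = []
        for other in ("pDE", "Rec"):
            if other not in rel or rel[other].values.size < 2:
                continue
            c = stats.contrast(rel["B2"].values, rel[other].values,
                               "rank-sum")
            contrasts.append({"analysis": "reliability",
                              "condition_A": "B2", "condition_B": other,
                              "test": c.test, "statistic": c.statistic,
                              "n": [c.n1, c.n2], "p": c.pvalue})
            fam.append(c.pvalue)
        for row, adj in zip(contrasts[-len(fam):], stats.bh_adjust(fam)):
            row["p_adj"] = float(adj)
    done()

    results = {
        "seed": master,
        "config": asdict(config),
        "n_responsive": {n: int(responsive[n].responsive.sum())
                         for n in names},
        "fraction_responsive": {n: responsive[n].fraction_responsive
                                for n in names},
        "n_tuned": {n: int(sum(f.tuned for f in fits[n].values()))
                    for n in names},
        "stability_median": {
            cond: {col: (float(np.median(df[col])) if len(df) else None)
                   for col in ("d_mu_theta", "d_bw_theta", "d_mu_sf",
                               "d_bw_sf")}
            for cond, df in deltas.items()},
        "similarity": similarity,
        "reliability_median": {
            n: (float(np.median(r.values)) if r.values.size else None)
            for n, r in rel.items()},
        "decoding": accuracy,
        "drift": drift,
        "contrasts": contrasts,
    }
    logger.info("stage timings: %s", timings)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "tables").mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(
            json.dumps(results, indent=1, sort_keys=True))
        for name in names:
            io.fits_to_frame(fits[name], name).to_csv(
                out / "tables" / f"fits_{name}.csv", index=False)
        for cond, df in deltas.items():
            df.to_csv(out / "tables" / f"deltas_{cond}.csv", index=False)
        (out / "report.md").write_text(_report_md(results))
    return results


def _report_md(results: dict) -> str:
    lines = ["# Synthetic dark-exposure experiment report", ""]
    lines.append(f"Master seed: {results['seed']}")
    lines.append("")
    lines.append("## Responsive / tuned neurons")
    for n, frac in results["fraction_responsive"].items():
        lines.append(f"- {n}: {frac:.2%} responsive, "
                     f"{results['n_tuned'][n]} tuned")
    lines.append("")
    lines.append("## Median stability deltas (per condition)")
    for cond, row in results["stability_median"].items():
        lines.append(f"- {cond}: " + ", ".join(
            f"{k}={v:.4g}" if v is not None else f"{k}=n/a"
            for k, v in row.items()))
    lines.append("")
    lines.append("## Signal-correlation similarity")
    for cond, v in results["similarity"].items():
        lines.append(f"- {cond}: {v:.3f}" if v is not None
                     else f"- {cond}: n/a")
    lines.append("")
    lines.append("## Median reliability per session")
    for n, v in results["reliability_median"].items():
        lines.append(f"- {n}: {v:.3f}" if v is not None else f"- {n}: n/a")
    lines.append("")
    lines.append("## Decoding accuracy (matched sessions)")
    for n, row in results["decoding"].items():
        lines.append(f"- {n}: accuracy {row['accuracy']:.3f} "
                     f"(chance {row['chance']:.4f})")
    lines.append("")
    lines.append("## Fixed-classifier drift")
    for cond, row in results["drift"].items():
        lines.append(f"- {cond}: acc_x1={row['acc_x1']:.3f} "
                     f"acc_x2={row['acc_x2']:.3f} drift={row['drift']:+.3f}")
    lines.append("")
    lines.append("## Condition contrasts")
    for c in results["contrasts"]:
        p_adj = c.get("p_adj")
        extra = f", p_adj={p_adj:.4g}" if p_adj is not None else ""
        lines.append(f"- {c['analysis']} ({c['condition_A']} vs "
                     f"{c['condition_B']}, {c['test']}): p={c['p']:.4g}"
                     f"{extra}")
    lines.append("")
    return "\n".join(lines)
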