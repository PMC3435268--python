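"""End-to-end orchestration: movement-related spectral change, coupling at
rest vs movement, coherence and spatial-overlap maps, plus the negative
control run.  Every stochastic step is driven by the config seed, and a run
manifest records config, input hash, and outputs so a rerun with the same
manifest is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import __version__
from .broadband import bandpower_broadband, psc_broadband, psc_decompose
from .coherence import (epoch_means, phase_coherence_map, project_coherence,
                        select_seed)
from .coupling import (condition_contrast, coupling_palette,
                       trial_coupling_stats)
from .data_model import EpochSet, PipelineConfig, RecordingSession
from .errors import ParameterError, ValidationError
from .preprocess import auto_exclude, common_average_reference
from .spectral import analytic_band, psd_snapshots
from .stats import signed_r2_with_p, spatial_overlap
from .synthetic import make_colored_noise, make_random_walk


@dataclass
class RunManifest:
    config: dict
    input_sha256: str
    seed: int
    version: str
    outputs: list[str]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True))


def _hash_session(session: RecordingSession) -> str:
    h = hashlib.sha256()
    h.update(session.samples.tobytes())
    h.update(np.float64(session.rate).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Trial segmentation
# ---------------------------------------------------------------------------

def condition_trials(session: RecordingSession, config: PipelineConfig):
    """Contiguous same-condition trial windows from the cue structure.

    Movement trials span [cue, cue + trial_movement_s) labeled by effector;
    each is followed by a rest trial of trial_rest_s.  Trials shorter than
    1 s or extending past the record are dropped.
    """
    rate = session.rate
    mlen = int(round(config.trial_movement_s * rate))
    rlen = int(round(config.trial_rest_s * rate))
    cues = session.events[session.events["label"] == "cue"]
    windows = []
    for _, row in cues.iterrows():
        s = int(row["sample"])
        if s + mlen <= session.n_samples and mlen >= rate:
            windows.append((s, mlen, str(row["effector"])))
        r0 = s + mlen
        if r0 + rlen <= session.n_samples and rlen >= rate:
            windows.append((r0, rlen, "rest"))
    return windows


def trials_for(windows, b, phi, condition: str):
    """(broadband, phase, valid) segments for one condition label.

    Trials with less than half their samples valid (wavelet edge regions at
    the record ends) are dropped.
    """
    segs = []
    for start, dur, label in windows:
        if label != condition:
            continue
        sl = slice(start, start + dur)
        if b.valid[sl].sum() < dur // 2:
            continue
        segs.append((b.values[sl], phi[sl], b.valid[sl]))
    return segs


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_full(session: RecordingSession, config: PipelineConfig, outdir,
             make_palettes: bool = True, verbose: bool = False) -> dict:
    """Run every stage and write the result tables + manifest to ``outdir``.

    Returns a dict of the in-memory results (DataFrames and palettes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def log(msg):
        if verbose:
            print(f"[{time.time() - t0:7.1f}s] {msg}")

    try:
        bad = auto_exclude(session)
        car = common_average_reference(session, bad)
    except ValidationError as exc:
        raise ValidationError(f"preprocess stage: {exc}") from exc
    rate = car.rate
    included = car.included_indices()
    ids = car.channels["id"].to_numpy()
    log(f"CAR done; {len(included)} channels included")

    # epochs around events
    effectors = sorted(set(car.events.loc[
        car.events["label"] == "movement_peak", "effector"]))
    rest_ep = EpochSet.around_events(car, "rest", config.epoch_duration_s)
    move_eps = {f: EpochSet.around_events(car, "movement_peak",
                                          config.epoch_duration_s, effector=f)
                for f in effectors}
    if len(rest_ep) == 0:
        raise ValidationError("coupling stage: session has no rest epochs")

    omit = config.line_noise_bands(config.psd_fmax)
    windows = condition_trials(session, config)

    bshift, betashift, zrows, crows = [], [], [], []
    palettes = {}
    bb_all = np.zeros_like(car.samples)
    rest_r2_broadband = {}

    for ch in included:
        x = car.samples[ch]
        # spectral snapshots + decomposition (per channel)
        all_eps = rest_ep
        for f in effectors:
            if len(move_eps[f]):
                labels = np.array([f] * len(move_eps[f]), dtype=object)
                all_eps = EpochSet(
                    np.concatenate([all_eps.starts, move_eps[f].starts]),
                    all_eps.duration,
                    np.concatenate([all_eps.labels, labels]))
        snaps = psd_snapshots(car, all_eps, channel=int(ch),
                              fmin=config.psd_fmin, fmax=min(
                                  config.psd_fmax, rate / 2 - 1),
                              omit_bands=omit)
        decomp = psc_decompose(snaps)
        if config.broadband_source == "psc":
            b = psc_broadband(x, rate, decomp, cycles=config.wavelet_cycles)
        else:
            b = bandpower_broadband(
                x, rate, config.broadband_band, config.line_noise_hz,
                config.line_noise_halfwidth_hz, config.filter_order)
        bb_all[ch] = b.values
        beta = analytic_band(x, config.beta_band, rate, config.filter_order)
        log(f"channel {ids[ch]}: broadband + beta done")

        # per-effector shifts (epoch means, movement vs rest)
        rest_bb = epoch_means(b.values, rest_ep)
        rest_beta = epoch_means(beta.amplitude, rest_ep)
        for f in effectors:
            if len(move_eps[f]) < 2 or len(rest_ep) < 2:
                continue
            r2, p = signed_r2_with_p(epoch_means(b.values, move_eps[f]),
                                     rest_bb)
            bshift.append((ids[ch], f, r2, p))
            r2, p = signed_r2_with_p(epoch_means(beta.amplitude, move_eps[f]),
                                     rest_beta)
            betashift.append((ids[ch], f, r2, p))

        # trial-wise coupling per condition
        if windows:
            rest_trials = trials_for(windows, b, beta.phase, "rest")
            if len(rest_trials) < 2:
                raise ValidationError("coupling stage: <2 rest trials")
            rest_stats = trial_coupling_stats(rest_trials, config.phase_bins,
                                              label="rest")
            zrows.append((ids[ch], "rest", rest_stats.z_mod,
                          rest_stats.phi_c, rest_stats.mean, rest_stats.sem,
                          rest_stats.p_value, rest_stats.n_trials))
            for f in effectors:
                segs = trials_for(windows, b, beta.phase, f)
                if len(segs) < 2:
                    continue
                mstats = trial_coupling_stats(segs, config.phase_bins, label=f)
                zrows.append((ids[ch], f, mstats.z_mod, mstats.phi_c,
                              mstats.mean, mstats.sem, mstats.p_value,
                              mstats.n_trials))
                r2, p = condition_contrast(mstats, rest_stats)
                crows.append((ids[ch], f, r2, p))
        if make_palettes:
            palettes[str(ids[ch])] = coupling_palette(
                b, x, rate, config.palette_grid, config.phase_bins,
                config.wavelet_cycles)
        log(f"channel {ids[ch]}: coupling done")

    results = {}
    results["broadband_shift"] = pd.DataFrame(
        bshift, columns=["channel", "effector", "signed_r2", "p"])
    results["beta_shift"] = pd.DataFrame(
        betashift, columns=["channel", "effector", "signed_r2", "p"])
    results["zmod"] = pd.DataFrame(
        zrows, columns=["channel", "condition", "z_mod", "phi_c",
                        "zeta_mean", "zeta_sem", "p", "n_trials"])
    results["coupling_contrast"] = pd.DataFrame(
        crows, columns=["channel", "effector", "signed_r2", "p"])

    # coherence map seeded at the strongest index-finger (or first) effector
    seed_eff = "index" if "index" in effectors else (
        effectors[0] if effectors else None)
    if seed_eff is not None and len(move_eps[seed_eff]) >= 2:
        sel = select_seed(car, bb_all, move_eps[seed_eff], rest_ep)
        cmap = phase_coherence_map(car, sel.channel, config.beta_band,
                                   rest_ep, config.filter_order)
        proj = project_coherence(cmap)
        results["coherence"] = pd.DataFrame({
            "channel": ids, "re": cmap.gamma.real, "im": cmap.gamma.imag,
            "magnitude": np.abs(cmap.gamma),
            "phase": np.angle(cmap.gamma), "projected": proj,
            "is_seed": np.arange(len(ids)) == sel.channel})
        log("coherence done")

    # digit-by-digit spatial overlap of the shift maps
    def shift_map(df, f):
        sub = df[df["effector"] == f].set_index("channel")["signed_r2"]
        return np.array([sub.get(i, 0.0) for i in ids])

    orows = []
    n_perm = min(config.n_permutations, 100_000)
    for i, f1 in enumerate(effectors):
        for f2 in effectors[i + 1:]:
            for name, df in (("broadband", results["broadband_shift"]),
                             ("beta", results["beta_shift"])):
                a, bvec = shift_map(df, f1), shift_map(df, f2)
                if not a.any() or not bvec.any():
                    continue
                res = spatial_overlap(a, bvec, n_perm=n_perm,
                                      seed=config.seed)
                orows.append((name, f1, f2, res.overlap, res.p_value,
                              res.n_permutations))
    results["overlap"] = pd.DataFrame(
        orows, columns=["measure", "effector_a", "effector_b", "overlap",
                        "p", "n_permutations"])
    log("overlap done")

    outputs = []
    for name in ("broadband_shift", "beta_shift", "zmod",
                 "coupling_contrast", "coherence", "overlap"):
        if name in results:
            path = outdir / f"{name}.csv"
            results[name].to_csv(path, index=False)
            outputs.append(path.name)
    for cid, pal in palettes.items():
        path = outdir / f"palette_{cid}.csv"
        pd.DataFrame(pal.means, index=pal.frequencies,
                     columns=np.round(pal.centers, 6)).to_csv(
            path, index_label="frequency_hz")
        outputs.append(path.name)
    results["palettes"] = palettes

    manifest = RunManifest(config=_config_dict(config),
                           input_sha256=_hash_session(session),
                           seed=config.seed, version=__version__,
                           outputs=sorted(outputs))
    manifest.write(outdir / "manifest.json")
    results["manifest"] = manifest
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


# ---------------------------------------------------------------------------
# Negative control
# ---------------------------------------------------------------------------

def run_negative_control(n_channels: int = 50, alpha=(0.01, 0.05),
                         duration_s: float = 60.0, rate: float = 500.0,
                         kind: str = "colored", chi: float = 2.0,
                         config: PipelineConfig | None = None,
                         seed: int = 0) -> dict:
    """Coupling false-positive rate on pure-noise channels.

    Each channel is an independent colored-noise (or random-walk) series;
    the full coupling path (band-power broadband, beta phase, 1-s trials,
    trial statistics) is applied and the fraction of channels significant
    at each alpha is compared with the 95% binomial interval around alpha.
    """
    if kind not in ("colored", "walk"):
        raise ParameterError("kind must be 'colored' or 'walk'")
    config = config or PipelineConfig()
    n = int(round(duration_s * rate))
    dur = int(round(config.epoch_duration_s * rate))
    alphas = np.atleast_1d(alpha)
    pvals = []
    for ch in range(n_channels):
        rng = np.random.default_rng(np.random.SeedSequence([seed, ch]))
        if kind == "colored":
            x = make_colored_noise(n, chi, rate, rng=rng)
        else:
            x = make_random_walk(n, rng=rng)
        b = bandpower_broadband(x, rate, config.broadband_band,
                                config.line_noise_hz,
                                config.line_noise_halfwidth_hz,
                                config.filter_order)
        phi = analytic_band(x, config.beta_band, rate,
                            config.filter_order).phase
        starts = np.arange(0, n - dur + 1, dur)
        trials = [(b.values[s:s + dur], phi[s:s + dur]) for s in starts]
        pvals.append(trial_coupling_stats(trials, config.phase_bins).p_value)
    pvals = np.array(pvals)
    report = {"kind": kind, "n_channels": n_channels, "p_values":
              pvals.tolist(), "alphas": {}}
    for a in alphas:
        k = int((pvals < a).sum())
        lo, hi = sstats.binom.interval(0.95, n_channels, a)
        report["alphas"][float(a)] = {
            "observed_rate": k / n_channels, "n_significant": k,
            "binomial_95_interval": [int(lo), int(hi)],
            "within_interval": bool(lo <= k <= hi)}
    return report
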