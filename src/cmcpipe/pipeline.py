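"""End-to-end study orchestration.

The processing pipeline mirrors the study design: (1) wavelet coherence on the
first 4 s of every trial, (2) per-participant peak coherence frequencies per
band, (3) wavelet coherence of the remaining 16 s, (4) AAFT-surrogate
significance mask, (5) lag-scanned directional coherence at the peak
frequencies, plus EEG power spectra and the PERMANOVA/NMDS group statistics on
six-dimensional CMC profiles.

`run_study` executes everything from a single `PipelineConfig`, writes tidy
CSV tables plus a provenance manifest, and returns the result bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .coherence import (
    CoherenceSpectrum,
    band_peak_frequency,
    coherence_from_windows,
    participant_peak_cf,
    window_coefficients,
)
from .config import PipelineConfig
from .directionality import (
    LagProfile,
    estimate_directional_cmc,
    smooth_lag_profile,
)
from .io import read_recording, write_recording
from .preprocess import preprocess_trial, segment_trial
from .recording import EEG, EMG, Trial
from .spectral import psd_boxcar
from .stats import (
    alt_gower_distance,
    assemble_profiles,
    nmds,
    pairwise_group_by_task,
    permanova,
)
from .surrogates import aaft, significance_mask
from .synthetic import make_cohort
from .wavelets import WaveletBank

log = logging.getLogger(__name__)

__all__ = ["run_study", "analyze_cohort", "simulate_trials", "group_statistics"]


def _bank(config: PipelineConfig) -> WaveletBank:
    w = config.wavelets
    return WaveletBank(scale=w.scale, q=w.q, r=w.r, j_range=w.j_range)


def simulate_trials(config: PipelineConfig) -> tuple[list[Trial], pd.DataFrame]:
    if config.synthetic is None:
        raise ValueError("config has no synthetic section")
    return make_cohort(config.synthetic)


def load_trials(config: PipelineConfig) -> tuple[list[Trial], pd.DataFrame]:
    """Read trials (two files per trial, one per modality) listed in design.csv."""
    base = Path(config.input_dir)
    design = pd.read_csv(base / "design.csv")
    suffix = ".edf" if config.input_format == "edf" else ".tsv"
    trials = []
    for _, row in design.iterrows():
        stem = f"{row.participant}_{row.task}_t{row.trial}"
        eeg = read_recording(base / f"{stem}_eeg{suffix}", config.input_format)
        emg = read_recording(base / f"{stem}_emg{suffix}", config.input_format)
        meta = {
            "participant": row.participant,
            "group": row.group,
            "task": row.task,
            "trial": int(row.trial),
        }
        eeg.meta.update(meta)
        emg.meta.update(meta)
        trials.append(Trial(eeg=eeg, emg=emg))
    return trials, design


def write_trials(trials, design, out_dir, format: str = "delimited") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".edf" if format == "edf" else ".tsv"
    for trial in trials:
        m = trial.meta
        stem = f"{m['participant']}_{m['task']}_t{m['trial']}"
        write_recording(trial.eeg, out / f"{stem}_eeg{suffix}", format)
        write_recording(trial.emg, out / f"{stem}_emg{suffix}", format)
    design.to_csv(out / "design.csv", index=False)


# ---------------------------------------------------------------------------
# trial-level analysis (pipeline steps 1-5 + PSD)
# ---------------------------------------------------------------------------

def _pairs(eeg_labels, emg_labels):
    return [(e, m) for e in eeg_labels for m in emg_labels]


def _muscle_set_of(config: PipelineConfig) -> dict[str, str]:
    lookup = {}
    for mset, labels in config.stats.muscle_sets.items():
        for lb in labels:
            lookup[lb] = mset
    return lookup


def analyze_cohort(
    trials: list[Trial], design: pd.DataFrame, config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """Steps 1-5 and PSD for every trial; returns tidy result tables."""
    fs = config.preprocess.fs_target
    bank = _bank(config)
    wincfg = config.windowing
    n_keep = wincfg.n_samples
    band_defs = config.band_definitions()
    bands = {name: band_defs[name] for name in config.analysis_bands}
    union_cfs = np.unique(
        np.concatenate([bank.cfs[b.mask(bank.cfs)] for b in bands.values()])
    )
    band_bank = WaveletBank(scale=bank.scale, cfs=union_cfs)
    band_masks = {name: b.mask(band_bank.cfs) for name, b in bands.items()}
    mset_of = _muscle_set_of(config)
    max_lag = int(round(config.directionality.max_lag_ms / 1000.0 * fs))

    master = np.random.SeedSequence(config.seed)
    trial_seeds = master.generate_state(len(trials)) % (2**31)

    # ---- pass 1: preprocess, segment, 4-s peak spectra, PSD ----
    prepped = []
    peak_rows = []
    psd_records = []
    for ti, trial in enumerate(trials):
        merged = preprocess_trial(trial, config.preprocess)
        peak_seg, analysis_seg = segment_trial(merged)
        meta = trial.meta
        eeg_labels = [l for l, r in zip(merged.labels, merged.roles) if r == EEG]
        emg_labels = [l for l, r in zip(merged.labels, merged.roles) if r == EMG]
        pairs = _pairs(eeg_labels, emg_labels)

        win4 = wincfg.for_segment(peak_seg.n_samples)
        w4 = {
            ch: window_coefficients(
                peak_seg.channel(ch)[: win4.n_samples], bank, win4, fs,
                dtype=np.float32,
            )
            for ch in merged.labels
        }
        for e, m in pairs:
            coh = coherence_from_windows(w4[e], w4[m])
            spec = CoherenceSpectrum(coh, bank.cfs, win4.n_windows, (e, m), "peak_4s")
            for bname, band in bands.items():
                peak_rows.append(
                    {
                        **meta,
                        "eeg": e,
                        "emg": m,
                        "band": bname,
                        "trial_peak_cf": band_peak_frequency(spec, band),
                    }
                )
        for ch in eeg_labels:
            psd_records.append(
                (meta, ch, psd_boxcar(merged.channel(ch), fs, config.psd_window_s, channel=ch))
            )
        prepped.append(
            {
                "meta": meta,
                "eeg_labels": eeg_labels,
                "emg_labels": emg_labels,
                "analysis": {ch: analysis_seg.channel(ch) for ch in merged.labels},
            }
        )

    # one peak frequency per participant and band, pooled over that
    # participant's trials and electrode pairs
    peak_df = pd.DataFrame(peak_rows)
    part_peaks = (
        peak_df.groupby(["participant", "band"], sort=False)["trial_peak_cf"]
        .apply(lambda v: participant_peak_cf(v.to_numpy(), bank))
        .rename("peak_cf")
        .reset_index()
    )
    peak_lookup = {
        (r.participant, r.band): r.peak_cf for r in part_peaks.itertuples()
    }

    # ---- pass 2: significance mask and lag-scanned directional CMC ----
    mask_rows = []
    cmc_rows = []
    scfg = config.surrogates
    for ti, rec in enumerate(prepped):
        meta = rec["meta"]
        pairs = _pairs(rec["eeg_labels"], rec["emg_labels"])
        x_keep = {lb: v[:n_keep] for lb, v in rec["analysis"].items()}
        wreal = {
            lb: window_coefficients(x, band_bank, wincfg, fs, dtype=np.float32)
            for lb, x in x_keep.items()
        }
        rng = np.random.default_rng(int(trial_seeds[ti]))
        wsur = {
            lb: window_coefficients(
                aaft(x, rng, scfg.n_surrogates), band_bank, wincfg, fs,
                dtype=np.float32,
            )
            for lb, x in x_keep.items()
        }
        retained_jobs = []
        for e, m in pairs:
            coh_real = coherence_from_windows(wreal[e], wreal[m])
            coh_sur = coherence_from_windows(wsur[e], wsur[m])
            for bname in bands:
                bm = float(coh_real[band_masks[bname]].mean())
                thr = scfg.threshold_of(coh_sur[:, band_masks[bname]].mean(axis=1))
                mask_rows.append(
                    {
                        **meta,
                        "eeg": e,
                        "emg": m,
                        "band": bname,
                        "band_mean": bm,
                        "threshold": thr,
                    }
                )
                if bm > thr:
                    retained_jobs.append((e, m, bname))

        # lag scans on the retained (pair, band) combinations, with a cache of
        # per-start wavelet coefficients shared across pairs and bands
        start_stack = {}
        coeff_cache = {}

        def _starts(lb):
            if lb not in start_stack:
                v = rec["analysis"][lb]
                start_stack[lb] = np.stack(
                    [v[s : s + n_keep] for s in range(max_lag + 1)]
                )
            return start_stack[lb]

        def _coeff(lb, cf):
            key = (lb, cf)
            if key not in coeff_cache:
                coeff_cache[key] = window_coefficients(
                    _starts(lb), bank.single(cf), wincfg, fs, dtype=np.float32
                )
            return coeff_cache[key]

        lags = np.arange(-max_lag, max_lag + 1)
        sx = np.maximum(0, -lags)
        sy = np.maximum(0, lags)
        for e, m, bname in retained_jobs:
            cf = peak_lookup[(meta["participant"], bname)]
            coh = coherence_from_windows(_coeff(e, cf)[sx], _coeff(m, cf)[sy])[:, 0]
            profile = LagProfile(lags * 1000.0 / fs, coh, cf, fs)
            est = estimate_directional_cmc(smooth_lag_profile(
                profile, config.directionality.smooth_span_ms
            ))
            cmc_rows.append(
                {
                    **meta,
                    "eeg": e,
                    "emg": m,
                    "pair": f"{e}-{m}",
                    "muscle_set": mset_of.get(m, "other"),
                    "band": bname,
                    "peak_cf": cf,
                    "afferent_cmc": est.afferent_cmc,
                    "efferent_cmc": est.efferent_cmc,
                    "afferent_delay_ms": est.afferent_delay_ms,
                    "efferent_delay_ms": est.efferent_delay_ms,
                }
            )

    cmc_df = pd.DataFrame(cmc_rows)
    if mask_rows:
        mask_df, retention = significance_mask(pd.DataFrame(mask_rows))
    else:
        mask_df, retention = pd.DataFrame(), pd.DataFrame()

    psd_rows = []
    for meta, ch, spectrum in psd_records:
        psd_rows.append(
            pd.DataFrame(
                {
                    "participant": meta["participant"],
                    "group": meta.get("group", ""),
                    "task": meta.get("task", ""),
                    "trial": meta.get("trial", 0),
                    "channel": ch,
                    "freq_hz": spectrum.freqs,
                    "power": spectrum.power,
                }
            )
        )
    psd_df = pd.concat(psd_rows, ignore_index=True) if psd_rows else pd.DataFrame()

    return {
        "peak_frequencies": part_peaks,
        "trial_peaks": peak_df,
        "mask": mask_df,
        "retention": retention,
        "directional_cmc": cmc_df,
        "psd": psd_df,
    }


def summarize_psd(psd_df: pd.DataFrame) -> pd.DataFrame:
    """Group-level PSD: mean and SEM across participants per group x task x
    channel (participant spectra are trial averages)."""
    if psd_df.empty:
        return psd_df
    per_part = (
        psd_df.groupby(["group", "task", "channel", "participant", "freq_hz"])["power"]
        .mean()
        .reset_index()
    )
    out = (
        per_part.groupby(["group", "task", "channel", "freq_hz"])["power"]
        .agg(mean_power="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_statistics(
    cmc_df: pd.DataFrame, config: PipelineConfig, seed: int | None = None
) -> dict:
    """PERMANOVA, task-wise pairwise contrasts and NMDS per muscle set and
    direction."""
    seed = config.seed if seed is None else seed
    results: dict = {"permanova": {}, "pairwise": {}, "nmds": {}, "profiles": {}}
    if cmc_df.empty:
        return results
    long_rows = []
    for direction in ("afferent", "efferent"):
        sub = cmc_df.copy()
        sub["direction"] = direction
        sub["cmc"] = sub[f"{direction}_cmc"]
        long_rows.append(sub)
    long_df = pd.concat(long_rows, ignore_index=True)

    for mset in sorted(cmc_df["muscle_set"].unique()):
        for direction in ("afferent", "efferent"):
            sel = long_df[(long_df.muscle_set == mset) & (long_df.direction == direction)]
            profiles = assemble_profiles(sel)
            key = f"{mset}_{direction}"
            results["profiles"][key] = profiles
            if profiles.empty:
                continue
            complete = profiles[profiles["complete"]].reset_index(drop=True)
            n_incomplete = int((~profiles["complete"]).sum())
            if n_incomplete:
                # repeated-measures permutation needs equal-sized participant
                # blocks, so a participant with any missing cell is dropped
                bad = profiles.loc[~profiles["complete"], "participant"].unique()
                complete = complete[~complete["participant"].isin(bad)].reset_index(
                    drop=True
                )
                log.info(
                    "%s: dropped %d incomplete profile(s) (participants %s)",
                    key, n_incomplete, list(bad),
                )
            if complete.empty or complete["group"].nunique() < 2:
                continue
            pair_cols = [
                c
                for c in complete.columns
                if c not in ("participant", "group", "task", "band", "direction",
                             "muscle_set", "complete")
            ]
            dist = alt_gower_distance(complete[pair_cols])
            design = complete[["participant", "group", "task", "band"]]
            try:
                results["permanova"][key] = permanova(
                    dist, design, terms=config.stats.terms, strata="participant",
                    n_perm=config.stats.n_perm, seed=seed,
                )
            except ValueError as exc:
                log.warning("PERMANOVA failed for %s: %s", key, exc)
                continue
            if direction == config.stats.pairwise_direction:
                try:
                    results["pairwise"][key] = pairwise_group_by_task(
                        dist, design, strata="participant",
                        n_perm=config.stats.n_perm, seed=seed,
                    )
                except ValueError as exc:
                    log.warning("pairwise contrast failed for %s: %s", key, exc)
            if not config.stats.run_nmds:
                continue
            coords, stress = nmds(
                dist, k=2, n_restarts=config.stats.nmds_restarts, seed=seed
            )
            nm = complete[["participant", "group", "task", "band"]].copy()
            nm["x"] = coords[:, 0]
            nm["y"] = coords[:, 1]
            nm["stress"] = stress
            results["nmds"][key] = nm
    return results


# ---------------------------------------------------------------------------
# run_study
# ---------------------------------------------------------------------------

def _config_hash(config: PipelineConfig) -> str:
    def sanitize(o):
        if isinstance(o, dict):
            return {str(k): sanitize(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [sanitize(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (str, int, float, bool)) or o is None:
            return o
        return str(o)

    blob = json.dumps(sanitize(asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_study(config: PipelineConfig, write: bool = True) -> dict:
    """Execute the full pipeline and (optionally) persist all tables."""
    if config.synthetic is not None:
        trials, design = simulate_trials(config)
    else:
        trials, design = load_trials(config)
    tables = analyze_cohort(trials, design, config)
    tables["psd_summary"] = summarize_psd(tables["psd"])
    stats = group_statistics(tables["directional_cmc"], config)

    bundle = {"design": design, **tables, **stats}
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        design.to_csv(out / "design.csv", index=False)
        for name in (
            "peak_frequencies", "trial_peaks", "mask", "retention",
            "directional_cmc", "psd_summary",
        ):
            df = tables[name]
            if isinstance(df, pd.DataFrame) and not df.empty:
                df.to_csv(out / f"{name}.csv", index=False)
        for kind in ("permanova", "pairwise", "nmds", "profiles"):
            for key, df in stats[kind].items():
                if isinstance(df, pd.DataFrame) and not df.empty:
                    df.to_csv(out / f"{kind}_{key}.csv", index=False)
        import scipy
        import sklearn

        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_trials": len(trials),
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "sklearn": sklearn.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
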