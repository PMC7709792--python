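"""Response characterization and model-vs-reference scoring.

Modulation transfer functions (MTFs: mean driven rate vs. AM frequency for
tone or noise carriers), tone-in-noise (TIN) rate-vs-SNR surfaces across
overall noise levels, MTF classification into band-enhanced (BE) /
band-suppressed (BS) / other, Pearson-correlation scoring of model against
reference curves, and a batch experiment driver that reproduces the full
panel set (MTFs, TIN, white-noise receptive field) for any cell spec.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .periphery import ANParams, CNParams
from .sfie import IECellSpec, driven_rate, simulate_cell
from .stimuli import (
    AMSpec,
    TINSpec,
    TIN_NOISE_LEVELS,
    TIN_SNR_GRID,
    mod_freq_grid,
    synth_am_noise,
    synth_am_tone,
    synth_tin,
    synth_white_noise,
)
from .wiener import (
    RFPeaks,
    ReceptiveField,
    decompose_kernel,
    estimate_h2,
    find_peaks,
    poisson_spikes,
    shuffled_kernel_stats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MTF",
    "TINResponse",
    "compute_mtf",
    "classify_mtf",
    "compute_tin",
    "tin_trends",
    "pearson_eval",
    "model_receptive_field",
    "run_experiment",
]

DEFAULT_FS = 100_000.0
AM_TONE_LEVEL_DB = 70.0
AM_NOISE_SPECTRUM_LEVEL_DB = 30.0
INTERIOR_BAND_HZ = (8.0, 128.0)


@dataclass
class MTF:
    """Modulation transfer function: mean driven rate vs. AM frequency."""

    mod_freqs_hz: np.ndarray
    rates: np.ndarray
    rate_unmod: float
    carrier: str
    rate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mod_freqs_hz = np.asarray(self.mod_freqs_hz, dtype=np.float64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if np.any(np.diff(self.mod_freqs_hz) <= 0):
            raise ValueError("modulation-frequency grid must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")


@dataclass
class TINResponse:
    """Mean driven rate per (overall noise level, SNR); SNR -inf = noise alone."""

    noise_levels_db: np.ndarray
    snrs_db: np.ndarray
    rates: np.ndarray  # level x SNR

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.shape != (len(self.noise_levels_db), len(self.snrs_db)):
            raise ValueError("rates matrix must be level x SNR")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")


def _cell_cf(spec: IECellSpec) -> float:
    return spec.excitatory[0].cf_hz


def compute_mtf(
    spec: IECellSpec,
    carrier: str = "noise",
    fm_grid: np.ndarray | None = None,
    n_reps: int = 5,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    an_params: ANParams | None = None,
    cn_params: CNParams | None = None,
) -> MTF:
    """Simulate the cell's MTF for a tone or noise carrier.

    Tone carriers sit at the cell's excitatory CF at 70 dB SPL and are
    deterministic (one rep); noise carriers (0.1–10 kHz, 30 dB SPL/Hz
    spectrum level) are averaged over ``n_reps`` seeds. The unmodulated
    carrier is always included. Levels are pre-attenuation; the simulation
    applies the standard 10-dB model-input attenuation.
    """
    if fm_grid is None:
        fm_grid = mod_freq_grid()
    cf = _cell_cf(spec)
    ss = np.random.SeedSequence(seed)

    def rate_for(fm: float | None, rep_seed: int) -> float:
        depth = 1.0 if fm is not None else 0.0
        fm_use = fm if fm is not None else 10.0  # depth 0: fm irrelevant
        if carrier == "tone":
            am = AMSpec("tone", fm_use, depth, carrier_freq_hz=cf, level_db=AM_TONE_LEVEL_DB)
            stim = synth_am_tone(am, fs=fs)
        else:
            am = AMSpec("noise", fm_use, depth, level_db=AM_NOISE_SPECTRUM_LEVEL_DB)
            stim = synth_am_noise(am, fs=fs, seed=rep_seed)
        return driven_rate(simulate_cell(spec, stim, an_params, cn_params))

    reps = 1 if carrier == "tone" else n_reps
    rep_seeds = ss.generate_state(reps * (len(fm_grid) + 1)).reshape(reps, -1)
    rates = np.empty((reps, len(fm_grid)))
    unmod = np.empty(reps)
    for r in range(reps):
        for k, fm in enumerate(fm_grid):
            rates[r, k] = rate_for(float(fm), int(rep_seeds[r, k] % 2**31))
        unmod[r] = rate_for(None, int(rep_seeds[r, -1] % 2**31))
    return MTF(
        mod_freqs_hz=fm_grid,
        rates=rates.mean(axis=0),
        rate_unmod=float(unmod.mean()),
        carrier=carrier,
        rate_sd=rates.std(axis=0) if reps > 1 else None,
    )


def classify_mtf(
    mtf: MTF,
    enh_factor: float = 1.2,
    sup_factor: float = 0.8,
    interior_band_hz: tuple[float, float] = INTERIOR_BAND_HZ,
) -> dict:
    """Classify an MTF as band-enhanced (BE), band-suppressed (BS) or other.

    BE: peak rate at an interior modulation frequency at least
    ``enh_factor`` times the unmodulated-carrier rate. BS: interior trough
    at most ``sup_factor`` times it. Invariant to uniform rate scaling.
    """
    if len(mtf.mod_freqs_hz) < 5:
        raise ValueError("need at least 5 grid points to classify an MTF")
    f = mtf.mod_freqs_hz
    interior = (f >= interior_band_hz[0]) & (f <= interior_band_hz[1])
    if not np.any(interior) or mtf.rate_unmod <= 0:
        return {"class": "other", "bmf_or_trough_hz": None}
    r_int = mtf.rates[interior]
    f_int = f[interior]
    peak, trough = np.max(r_int), np.min(r_int)
    if peak >= enh_factor * mtf.rate_unmod:
        return {"class": "BE", "bmf_or_trough_hz": float(f_int[np.argmax(r_int)])}
    if trough <= sup_factor * mtf.rate_unmod:
        return {"class": "BS", "bmf_or_trough_hz": float(f_int[np.argmin(r_int)])}
    return {"class": "other", "bmf_or_trough_hz": None}


def compute_tin(
    spec: IECellSpec,
    levels_db: tuple = TIN_NOISE_LEVELS,
    snrs_db: tuple = TIN_SNR_GRID,
    n_reps: int = 5,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    an_params: ANParams | None = None,
    cn_params: CNParams | None = None,
) -> TINResponse:
    """Tone-in-noise rate surface: tone at CF, 1/3-octave band centered at CF."""
    cf = _cell_cf(spec)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_reps * len(levels_db)).reshape(len(levels_db), n_reps)
    rates = np.zeros((len(levels_db), len(snrs_db)))
    for i, lvl in enumerate(levels_db):
        for r in range(n_reps):
            # one noise seed shared across the SNR column (paired comparison)
            noise_seed = int(seeds[i, r] % 2**31)
            for j, snr in enumerate(snrs_db):
                tin = TINSpec(cf, cf, float(lvl), float(snr))
                stim = synth_tin(tin, fs=fs, seed=noise_seed)
                rates[i, j] += driven_rate(
                    simulate_cell(spec, stim, an_params, cn_params)
                )
    rates /= n_reps
    return TINResponse(
        noise_levels_db=np.asarray(levels_db, float),
        snrs_db=np.asarray(snrs_db, float),
        rates=rates,
    )


def tin_trends(tin: TINResponse) -> np.ndarray:
    """Spearman rank correlation of rate vs. SNR (tone present) per noise level.

    Negative trends are the BE prediction (tone flattens the envelope,
    lowering a fluctuation-driven rate); positive trends the BS prediction.
    """
    finite = np.isfinite(tin.snrs_db)
    out = np.empty(len(tin.noise_levels_db))
    for i in range(len(out)):
        rho = stats.spearmanr(tin.snrs_db[finite], tin.rates[i, finite]).statistic
        out[i] = rho if np.isfinite(rho) else 0.0
    return out


def pearson_eval(model_curve, reference_curve) -> dict:
    """Pearson r and two-sided p (t transform, n-2 df) between two curves.

    Zero variance in either input leaves r undefined: the result is flagged
    (``valid = False``) so callers can exclude it from across-level means.
    """
    x = np.asarray(model_curve, float)
    y = np.asarray(reference_curve, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("curves must have equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("curves must be finite")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return {"r": np.nan, "p": np.nan, "valid": False}
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "valid": True}


def score_tin(model: TINResponse, reference: TINResponse) -> dict:
    """Per-noise-level Pearson scores plus the across-level mean r.

    The mean over valid levels is the summary statistic used when comparing
    model variants for one neuron.
    """
    per_level = []
    for i in range(len(model.noise_levels_db)):
        per_level.append(pearson_eval(model.rates[i], reference.rates[i]))
    rs = [s["r"] for s in per_level if s["valid"]]
    return {
        "per_level": per_level,
        "mean_r": float(np.mean(rs)) if rs else np.nan,
        "n_valid": len(rs),
    }


def compare_model_variants(scores_a, scores_b) -> dict:
    """Paired comparison of two model variants across a population of cells.

    ``scores_a``/``scores_b`` are per-cell summary correlations (one value
    per cell, same cells in the same order — e.g. each cell's across-level
    mean TIN r, or its MTF r). Returns the paired t statistic and p-value
    plus the mean difference. With per-neuron reference data this is how
    one asks whether a modification improves on the baseline circuit.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length score vectors (>= 2 cells)")
    ok = np.isfinite(a) & np.isfinite(b)
    res = stats.ttest_rel(a[ok], b[ok])
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_diff": float(np.mean(a[ok] - b[ok])),
        "n": int(ok.sum()),
    }


def significant_fraction(score_sets, alpha: float = 0.05, min_significant: int = 1) -> float:
    """Fraction of cells whose scores are significant in >= ``min_significant``
    of their panels; each element of ``score_sets`` is one cell's list of
    ``pearson_eval`` results."""
    hits = 0
    for scores in score_sets:
        n_sig = sum(1 for s in scores if s.get("valid", True) and s["p"] < alpha)
        hits += n_sig >= min_significant
    return hits / len(score_sets)


def model_receptive_field(
    spec: IECellSpec,
    duration_s: float = 60.0,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    lag_window_s: float = 0.016,
    use_eig_floor: bool = True,
    an_params: ANParams | None = None,
    cn_params: CNParams | None = None,
) -> tuple[ReceptiveField, RFPeaks, dict]:
    """Closed-loop receptive field of a model cell.

    White noise -> model rate -> Poisson spikes -> second-order kernel ->
    eigendecomposition -> smoothed peaks; the same pipeline applied to
    recorded neurons, run on the model's own output. Returns the RF, its
    peaks, and diagnostics (spike count, eigenvalue floor).
    """
    ss = np.random.SeedSequence(seed)
    s_noise, s_spk, s_surr = (int(v % 2**31) for v in ss.generate_state(3))
    stim = synth_white_noise(fs=fs, seed=s_noise, duration_s=duration_s)
    resp = simulate_cell(spec, stim, an_params, cn_params)
    spikes = poisson_spikes(resp, seed=s_spk)
    k2 = estimate_h2(stim, spikes, lag_window_s=lag_window_s)
    floor = 0.0
    if use_eig_floor:
        floor = shuffled_kernel_stats(stim, spikes, seed=s_surr)["eig_floor"]
    rf = decompose_kernel(k2, eig_threshold=floor)
    peaks = find_peaks(rf)
    diag = {"n_spikes": spikes.n_spikes, "eig_floor": floor, "mean_rate": resp.mean_rate()}
    return rf, peaks, diag


def _write_csv(path: Path, header: str, columns: list[np.ndarray]) -> None:
    data = np.column_stack(columns)
    np.savetxt(path, data, fmt="%.10g", delimiter=",", header=header, comments="")


def run_experiment(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Batch driver: MTFs, TIN surface, white-noise RF and optional scoring.

    ``config`` is a dict or a YAML path with keys ``cell`` (an IECellSpec
    dict), ``seed``, and optional ``mtf``, ``tin``, ``rf`` sub-dicts plus a
    ``reference`` block of curves to score against. Panels that fail are
    reported in the summary and the run continues. Output CSV/JSON files
    are written with fixed formatting so a rerun with the same seed is
    byte-identical.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    spec = IECellSpec.from_dict(config["cell"])
    seed = int(config.get("seed", 0))
    out = Path(out_dir) if out_dir else Path(config.get("out_dir", "sfie_ic_out"))
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"cell": spec.name or spec.modification, "seed": seed, "panels": {}}

    def run_panel(name, fn):
        try:
            summary["panels"][name] = fn()
        except Exception as exc:  # continue on per-panel failure
            logger.exception("panel %s failed", name)
            summary["panels"][name] = {"error": f"{type(exc).__name__}: {exc}"}

    mtf_cfg = config.get("mtf", {})
    tin_cfg = config.get("tin", {})
    rf_cfg = config.get("rf", {})
    reference = config.get("reference", {})
    results: dict = {}

    def panel_mtf(carrier):
        def _run():
            grid = mtf_cfg.get("fm_grid")
            mtf = compute_mtf(
                spec,
                carrier=carrier,
                fm_grid=np.asarray(grid, float) if grid is not None else None,
                n_reps=int(mtf_cfg.get("n_reps", 5)),
                seed=seed,
            )
            results[f"mtf_{carrier}"] = mtf
            _write_csv(
                out / f"mtf_{carrier}.csv",
                "mod_freq_hz,rate",
                [mtf.mod_freqs_hz, mtf.rates],
            )
            info = classify_mtf(mtf)
            info["rate_unmod"] = mtf.rate_unmod
            ref = reference.get(f"mtf_{carrier}")
            if ref is not None:
                info["score"] = pearson_eval(mtf.rates, np.asarray(ref, float))
            return info

        return _run

    def panel_tin():
        tin = compute_tin(
            spec,
            levels_db=tuple(tin_cfg.get("levels_db", TIN_NOISE_LEVELS)),
            snrs_db=tuple(
                float(s) for s in tin_cfg.get("snrs_db", TIN_SNR_GRID)
            ),
            n_reps=int(tin_cfg.get("n_reps", 5)),
            seed=seed,
        )
        results["tin"] = tin
        _write_csv(
            out / "tin.csv",
            "noise_level_db," + ",".join(f"snr_{s:g}" for s in tin.snrs_db),
            [tin.noise_levels_db] + [tin.rates[:, j] for j in range(len(tin.snrs_db))],
        )
        info = {"trends": [float(t) for t in tin_trends(tin)]}
        ref = reference.get("tin")
        if ref is not None:
            ref_tin = TINResponse(tin.noise_levels_db, tin.snrs_db, np.asarray(ref, float))
            info["score"] = score_tin(tin, ref_tin)
        return info

    def panel_rf():
        rf, peaks, diag = model_receptive_field(
            spec,
            duration_s=float(rf_cfg.get("duration_s", 60.0)),
            seed=seed,
            use_eig_floor=bool(rf_cfg.get("use_eig_floor", True)),
        )
        np.savetxt(out / "rf.csv", rf.rf, fmt="%.6g", delimiter=",")
        info = {
            "peaks_exc": [list(p) for p in peaks.exc[:3]],
            "peaks_inh": [list(p) for p in peaks.inh[:3]],
            **diag,
        }
        with open(out / "rf_peaks.json", "w") as fh:
            json.dump(info, fh, indent=2, default=float)
        return info

    if mtf_cfg.get("enabled", True):
        run_panel("mtf_noise", panel_mtf("noise"))
        if mtf_cfg.get("tone", True):
            run_panel("mtf_tone", panel_mtf("tone"))
    if tin_cfg.get("enabled", True):
        run_panel("tin", panel_tin)
    if rf_cfg.get("enabled", False):
        run_panel("rf", panel_rf)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
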