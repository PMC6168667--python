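"""ICA decomposition of scalp epochs and automated artifactual-component
classification and removal.

The decomposition is natural-gradient Infomax (the :func:`mne.preprocessing.
infomax` implementation, annealing learning rate, seeded) on EEGLAB-style
sphered data; only the 11 scalp channels enter the decomposition, while
EOG/EMG1/EMG2 serve purely as classification references.  Components are
scored with five criteria in the style of automated IC-advisory tools:

* temporal autocorrelation at a 20 ms lag (low → muscle-like),
* focal scalp topography (one electrode dominating, z > 3.5),
* focal trial activity (one epoch dominating, z > 10),
* stimulus-locked signal-to-noise of the component ERP (post/pre SD < 1 →
  no event-locked content),
* absolute correlation with the EOG/EMG reference channels (r > 0.2).

The final artifact decision is the union of the criteria by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .erp import EpochSet
from .io_events import ms_window_to_samples, logger


@dataclass
class ClassifierConfig:
    """Thresholds of the five component-classification criteria."""

    autocorr_lag_ms: float = 20.0
    autocorr_threshold: float | str = "auto"   # "auto" = mean - 2 SD across comps
    focal_topo_z_threshold: float = 3.5
    focal_trial_z_threshold: float = 10.0
    snr_poi_ms: tuple[float, float] | None = None   # None -> (0, epoch end)
    snr_bl_ms: tuple[float, float] | None = None    # None -> (epoch start, 0)
    snr_ratio_threshold: float = 1.0
    ref_corr_threshold: float = 0.2
    combine: str = "union"                     # or "vote" (majority)

    @classmethod
    def from_pipeline(cls, cfg) -> "ClassifierConfig":
        return cls(cfg.autocorr_lag_ms, cfg.autocorr_threshold,
                   cfg.focal_topo_z_threshold, cfg.focal_trial_z_threshold,
                   None, None, cfg.snr_ratio_threshold, cfg.ref_corr_threshold,
                   cfg.classifier_combine)


@dataclass
class ICADecomposition:
    """Unmixing/mixing matrices and component activations.

    ``activations = unmixing @ X`` exactly, where X is the concatenated
    (epochs joined along time) scalp data the ICA was fit on, and
    ``unmixing @ mixing ≈ I``.  Components are ordered by descending
    projected variance, with signs fixed so each mixing column's largest
    absolute weight is positive.
    """

    unmixing: np.ndarray          # components x channels
    mixing: np.ndarray            # channels x components
    activations: np.ndarray       # components x (epochs * samples)
    channel_names: list[str]
    n_epochs: int
    n_samples: int                # per epoch
    rate: float
    window_ms: tuple[float, float]
    baseline_window_ms: tuple[float, float]
    seed: int
    n_iter: int

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def epoch_activations(self) -> np.ndarray:
        """Activations reshaped to ``components × epochs × samples``."""
        return self.activations.reshape(self.n_components, self.n_epochs, self.n_samples)


def fit_ica(epochs: EpochSet, seed: int, max_iter: int = 512,
            w_change: float = 1e-7, extended: bool = False,
            train_decim: int = 1, block: int = 1024) -> ICADecomposition:
    """Fit Infomax ICA on the concatenated epochs.

    The unmixing matrix is trained on a temporally decimated copy
    (``train_decim``; the full concatenation is far beyond the ~20·ch²
    samples needed for a stable estimate) after centering and sphering;
    activations are then computed on the full-resolution data.  ``block``
    is the stochastic-gradient minibatch size.  Deterministic given
    ``seed``.
    """
    from mne.preprocessing import infomax

    X = epochs.data.transpose(1, 0, 2).reshape(len(epochs.channel_names), -1)
    n_ch, n_total = X.shape
    if n_total < 20 * n_ch * n_ch:
        logger.warning("only %d samples for %d channels; ICA may be unstable",
                       n_total, n_ch)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = np.cov(Xc)
    if np.linalg.matrix_rank(cov) < n_ch:
        raise ValueError(
            "scalp data are rank deficient; exclude interpolated/duplicate "
            "channels before ICA"
        )
    sphere = 2.0 * linalg.inv(linalg.sqrtm(cov).real)
    train = (sphere @ Xc)[:, ::max(1, int(train_decim))]
    W, n_iter = infomax(train.T, extended=extended, max_iter=max_iter,
                        w_change=w_change, block=max(8, min(block, train.shape[1] // 4)),
                        rng=np.random.default_rng(int(seed)),
                        return_n_iter=True, verbose="error")
    unmixing = W @ sphere
    mixing = np.linalg.pinv(unmixing)
    act = unmixing @ X

    # order by descending projected variance, fix signs
    proj_var = (mixing ** 2).sum(axis=0) * act.var(axis=1)
    order = np.argsort(proj_var)[::-1]
    unmixing, mixing, act = unmixing[order], mixing[:, order], act[order]
    for i in range(n_ch):
        j = int(np.argmax(np.abs(mixing[:, i])))
        if mixing[j, i] < 0:
            mixing[:, i] *= -1.0
            unmixing[i] *= -1.0
            act[i] *= -1.0

    return ICADecomposition(unmixing, mixing, act, list(epochs.channel_names),
                            len(epochs), epochs.n_samples, epochs.rate,
                            epochs.window_ms, epochs.baseline_window_ms,
                            int(seed), int(n_iter))


# ---------------------------------------------------------------------------
# Per-criterion scores
# ---------------------------------------------------------------------------

def score_autocorrelation(dec: ICADecomposition, lag_ms: float = 20.0,
                          rate: float | None = None) -> np.ndarray:
    """Pearson autocorrelation of each component at ``lag_ms``, computed per
    epoch and averaged.  A constant activation has r = 1 by convention (it
    is certainly not muscle noise)."""
    rate = dec.rate if rate is None else rate
    lag = int(np.round(lag_ms * rate / 1000.0))
    if lag < 1:
        raise ValueError(f"lag of {lag_ms} ms is below one sample at {rate} Hz")
    ea = dec.epoch_activations()
    a = ea[:, :, :-lag]
    b = ea[:, :, lag:]
    am = a - a.mean(axis=2, keepdims=True)
    bm = b - b.mean(axis=2, keepdims=True)
    num = (am * bm).sum(axis=2)
    den = np.sqrt((am ** 2).sum(axis=2) * (bm ** 2).sum(axis=2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    return r.mean(axis=1)


def _max_z(values: np.ndarray) -> np.ndarray:
    """Max z-score along the last axis (population SD); zero-variance rows
    give z = 0."""
    mean = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z.max(axis=-1)


def score_focal_topography(dec: ICADecomposition) -> np.ndarray:
    """Max z-score of the absolute mixing weights across channels, per
    component; a focal (single-electrode) topography scores high."""
    if dec.mixing.shape[0] < 3:
        raise ValueError("focal topography needs at least 3 channels")
    return _max_z(np.abs(dec.mixing.T))


def score_focal_trial(dec: ICADecomposition) -> np.ndarray:
    """Max z-score across epochs of the per-epoch maximum absolute
    activation; a component active in one trial only scores high."""
    if dec.n_epochs < 5:
        raise ValueError("focal trial activity needs at least 5 epochs")
    per_epoch_max = np.abs(dec.epoch_activations()).max(axis=2)
    return _max_z(per_epoch_max)


def score_snr(dec: ICADecomposition,
              poi_ms: tuple[float, float] | None = None,
              bl_ms: tuple[float, float] | None = None) -> np.ndarray:
    """SD of the component ERP after stimulus onset divided by SD before it
    (component ERP baselined with the EEG epoch convention).  A zero
    pre-stimulus SD gives +inf (perfectly stimulus-locked)."""
    start, stop = ms_window_to_samples(dec.window_ms, dec.rate)
    poi_ms = poi_ms or (0.0, dec.window_ms[1])
    bl_ms = bl_ms or (dec.window_ms[0], 0.0)
    comp_erp = dec.epoch_activations().mean(axis=1)   # components x samples
    b0, b1 = ms_window_to_samples(dec.baseline_window_ms, dec.rate)
    comp_erp = comp_erp - comp_erp[:, b0 - start: b1 - start].mean(axis=1, keepdims=True)

    def sd_in(window):
        w0, w1 = ms_window_to_samples(window, dec.rate)
        return comp_erp[:, w0 - start: w1 - start].std(axis=1)

    post, pre = sd_in(poi_ms), sd_in(bl_ms)
    with np.errstate(divide="ignore"):
        return np.where(pre > 0, post / np.where(pre > 0, pre, 1.0), np.inf)


def score_reference_correlation(dec: ICADecomposition,
                                refs: dict[str, np.ndarray]) -> np.ndarray:
    """Max absolute Pearson correlation of each component's concatenated
    activation with each epoch-matched reference channel (EOG/EMG1/EMG2).
    Zero-variance references are skipped with a warning."""
    best = np.zeros(dec.n_components)
    used = 0
    for name, ref in refs.items():
        r = np.asarray(ref, dtype=np.float64).reshape(-1)
        if r.shape[0] != dec.activations.shape[1]:
            raise ValueError(f"reference {name!r} is not epoch-aligned to the activations")
        if r.std() == 0:
            logger.warning("reference channel %s has zero variance; skipped", name)
            continue
        used += 1
        rc = (r - r.mean()) / r.std()
        a = dec.activations
        am = a - a.mean(axis=1, keepdims=True)
        sd = am.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs((am * rc).mean(axis=1) / np.where(sd > 0, sd, 1.0))
        corr = np.where(sd > 0, corr, 0.0)
        best = np.maximum(best, corr)
    if used == 0:
        logger.warning("no usable reference channels; reference correlations are 0")
    return best


# ---------------------------------------------------------------------------
# Classification and removal
# ---------------------------------------------------------------------------

@dataclass
class ComponentScores:
    """Per-component criterion scores, flags and the final decision.

    ``table`` columns: component, autocorr_r, focal_topo_z, focal_trial_z,
    snr_ratio, max_ref_corr, flag_* per criterion, final_artifact.
    """

    table: pd.DataFrame
    autocorr_threshold_used: float

    @property
    def final_artifact(self) -> np.ndarray:
        return self.table["final_artifact"].to_numpy()


def score_components(dec: ICADecomposition, refs: dict[str, np.ndarray],
                     cfg: ClassifierConfig | None = None) -> ComponentScores:
    """Compute all five criterion scores and flags for every component."""
    cfg = cfg or ClassifierConfig()
    autocorr = score_autocorrelation(dec, cfg.autocorr_lag_ms)
    topo_z = score_focal_topography(dec)
    trial_z = score_focal_trial(dec)
    snr = score_snr(dec, cfg.snr_poi_ms, cfg.snr_bl_ms)
    ref_corr = score_reference_correlation(dec, refs)

    if cfg.autocorr_threshold == "auto":
        thr = float(autocorr.mean() - 2.0 * autocorr.std())
    else:
        thr = float(cfg.autocorr_threshold)

    df = pd.DataFrame({
        "component": np.arange(dec.n_components),
        "autocorr_r": autocorr,
        "focal_topo_z": topo_z,
        "focal_trial_z": trial_z,
        "snr_ratio": snr,
        "max_ref_corr": ref_corr,
        "flag_autocorr": autocorr < thr,
        "flag_focal_topo": topo_z > cfg.focal_topo_z_threshold,
        "flag_focal_trial": trial_z > cfg.focal_trial_z_threshold,
        "flag_snr": snr < cfg.snr_ratio_threshold,
        "flag_ref_corr": ref_corr > cfg.ref_corr_threshold,
    })
    scores = ComponentScores(df, thr)
    return classify_components(scores, cfg.combine)


def classify_components(scores: ComponentScores, combine: str = "union") -> ComponentScores:
    """Set the final artifact decision from the criterion flags: union (any
    flag) by default, or majority vote."""
    flags = scores.table[[c for c in scores.table.columns if c.startswith("flag_")]]
    if combine == "union":
        final = flags.any(axis=1)
    elif combine == "vote":
        final = flags.sum(axis=1) >= int(np.ceil((flags.shape[1] + 1) / 2))
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    df = scores.table.copy()
    df["final_artifact"] = final.to_numpy()
    return ComponentScores(df, scores.autocorr_threshold_used)


def remove_components(epochs: EpochSet, dec: ICADecomposition,
                      scores: ComponentScores) -> EpochSet:
    """Reconstruct the epochs from the non-artifactual components only.

    Raises when every component is flagged (that signals thresholds in need
    of review, not a cleanable recording).
    """
    if list(epochs.channel_names) != dec.channel_names:
        raise ValueError("epochs do not match the channels the ICA was fit on")
    keep = ~scores.final_artifact
    if not keep.any():
        raise ValueError(
            "all components were classified artifactual; review the "
            "classifier thresholds before removing components"
        )
    cleaned = dec.mixing[:, keep] @ dec.activations[keep]
    data = cleaned.reshape(len(dec.channel_names), dec.n_epochs, dec.n_samples)
    return EpochSet(data.transpose(1, 0, 2), epochs.conditions,
                    list(epochs.channel_names), epochs.rate, epochs.window_ms,
                    epochs.baseline_window_ms, epochs.event_index)
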