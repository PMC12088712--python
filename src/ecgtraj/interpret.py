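"""Decision-basis visualization: Grad-CAM time maps fused with transformer
lead-attention weights, QRS detection, RR normalization to a 1 s beat grid,
and class-averaged attention maps.

Two-step heatmap construction:

1. the class-token -> lead-token attention row of the transformer encoder
   (final layer, head-averaged, normalized to sum to 1) weighs the leads;
2. Grad-CAM at the last convolutional feature map of the shared lead encoder
   (channel-gradient-weighted, rectified, linearly upsampled to the window
   length) localizes evidence in time within each lead.

Row ``l`` of the fused heatmap is ``attention[l] * gradcam[l]``, globally
max-normalized to [0, 1].  For cross-patient averaging, R peaks are detected
with a Pan-Tompkins-style energy detector, each R-R segment of the heatmap is
linearly resampled to exactly 500 samples (1 s at 500 Hz), and beats are
averaged element-wise per class.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .labeling import TrajectorySample
from .model import LeadTokenNetwork
from .preprocess import WindowSpec, concat_dual, extract_window

logger = logging.getLogger(__name__)

BEAT_SAMPLES = 500          # 1 s at 500 Hz
REFRACTORY_S = 0.2


@dataclass
class AttentionHeatmap:
    """Per-lead, per-sample relevance in [0, 1] (global max = 1 unless all-zero)."""
    values: np.ndarray                  # (n_leads, W)
    target_class: int | None = None
    lead_weights: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("heatmap values must be non-negative")


@dataclass
class QrsPeaks:
    indices: np.ndarray                 # sample indices of R peaks
    fs: float
    detection_lead: int = 1             # lead II by default

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.indices.size >= 2 and np.min(np.diff(self.indices)) < REFRACTORY_S * self.fs:
            raise ValueError("peaks violate the 200 ms refractory period")


@dataclass
class AveragedAttentionMap:
    values: np.ndarray                  # (n_leads, 500)
    class_label: str
    n_samples: int
    n_beats: int

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


# -------------------------------------------------------------------------
# Grad-CAM
# -------------------------------------------------------------------------

def gradcam_time_map(net: LeadTokenNetwork, window: np.ndarray,
                     target: int | None = None) -> np.ndarray:
    """Non-negative (n_leads, W) Grad-CAM map for one window.

    ``target`` selects the class logit (3-class head; default: predicted
    class).  For the regression head the scalar output itself is the target.
    Per lead, channel weights are the time-mean of the gradient of the target
    w.r.t. the final backbone feature map; the weighted activation sum is
    rectified at zero and linearly upsampled to W samples.
    """
    cfg = net.config
    net.eval()
    out = net.forward(np.ascontiguousarray(window[None]))
    if cfg.head == "classification_3":
        t = int(np.argmax(out[0])) if target is None else int(target)
        dout = np.zeros_like(out)
        dout[0, t] = 1.0
    else:
        dout = np.ones_like(out)
    net.zero_grad()
    net.backward(dout)
    net.zero_grad()     # gradients were only needed for the retained feature map
    acts = net.backbone.last_feature            # (L, T', C)
    grads = net.backbone.last_feature_grad
    w = grads.mean(axis=1)                      # (L, C)
    cam = np.maximum(np.einsum("lc,ltc->lt", w, acts), 0.0)
    n_leads, t_feat = cam.shape
    width = window.shape[-1]
    xp = np.linspace(0, width - 1, t_feat)
    up = np.empty((n_leads, width))
    xs = np.arange(width)
    for lead in range(n_leads):
        up[lead] = np.interp(xs, xp, cam[lead])
    return up


def fuse_heatmap(gradcam: np.ndarray, lead_weights: np.ndarray,
                 target_class: int | None = None) -> AttentionHeatmap:
    """Scale each Grad-CAM row by its lead-attention weight and max-normalize."""
    gradcam = np.asarray(gradcam, dtype=float)
    weights = np.asarray(lead_weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("lead attention weights must be non-negative")
    if weights.shape != (gradcam.shape[0],):
        raise ValueError(f"need one weight per lead, got {weights.shape} "
                         f"for {gradcam.shape[0]} leads")
    total = weights.sum()
    if total > 0:
        weights = weights / total
    fused = weights[:, None] * gradcam
    peak = fused.max()
    if peak > 0:
        fused = fused / peak
    return AttentionHeatmap(values=fused, target_class=target_class,
                            lead_weights=weights)


def sample_heatmap(net: LeadTokenNetwork, window: np.ndarray,
                   target: int | None = None) -> AttentionHeatmap:
    """End-to-end fused heatmap for one (n_leads, W) window."""
    cam = gradcam_time_map(net, window, target)     # also runs the forward pass
    weights = net.capture_attention()[0]
    return fuse_heatmap(cam, weights, target_class=target)


# -------------------------------------------------------------------------
# QRS detection (Pan-Tompkins-style energy detector)
# -------------------------------------------------------------------------

def detect_qrs(x: np.ndarray, fs: float, detection_lead: int = 1) -> QrsPeaks:
    """R-peak detection on a single-lead mV trace.

    Band-pass 5-15 Hz, differentiate, square, 150 ms moving-window integrate,
    adaptive signal/noise threshold with a 200 ms refractory period; accepted
    peaks are refined to the local |signal| maximum within +/-50 ms.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2 * fs:
        raise ValueError(f"need at least 2 s of signal, got {x.size / fs:.2f} s")
    if np.ptp(x) == 0:
        logger.warning("flat signal: no QRS peaks found")
        return QrsPeaks(indices=np.array([], dtype=int), fs=fs,
                        detection_lead=detection_lead)
    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    dist = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integ, distance=dist)
    if cand.size == 0:
        logger.warning("no candidate peaks found")
        return QrsPeaks(indices=np.array([], dtype=int), fs=fs,
                        detection_lead=detection_lead)
    spki = 0.25 * float(integ.max())
    npki = 0.5 * float(integ.mean())
    accepted = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[p] >= thr:
            spki = 0.125 * integ[p] + 0.875 * spki
            accepted.append(int(p))
        else:
            npki = 0.125 * integ[p] + 0.875 * npki

    # refine to the local |x| maximum within +/-50 ms, re-enforce refractory
    half = int(round(0.05 * fs))
    refined: list[int] = []
    for p in accepted:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        r = lo + int(np.argmax(np.abs(x[lo:hi])))
        if refined and r - refined[-1] < dist:
            if np.abs(x[r]) > np.abs(x[refined[-1]]):
                refined[-1] = r
        elif not refined or r > refined[-1]:
            refined.append(r)
    return QrsPeaks(indices=np.array(refined, dtype=int), fs=fs,
                    detection_lead=detection_lead)


# -------------------------------------------------------------------------
# RR normalization and averaging
# -------------------------------------------------------------------------

def rr_normalize(values: np.ndarray, peaks: QrsPeaks, fs: float = 500.0
                 ) -> list[np.ndarray]:
    """Resample each R-R segment of an (n_leads, W) map to exactly 500
    samples (1 s at 500 Hz beat grid); returns one (n_leads, 500) array per
    beat.  Constant maps are fixed points; a 500-sample RR is returned
    unchanged."""
    values = np.asarray(values, dtype=float)
    idx = peaks.indices
    if idx.size < 2:
        raise ValueError("need at least 2 R peaks to delimit a beat")
    xs = np.arange(values.shape[1])
    beats = []
    for r0, r1 in zip(idx[:-1], idx[1:]):
        tgt = r0 + (r1 - r0) * np.arange(BEAT_SAMPLES) / BEAT_SAMPLES
        beat = np.empty((values.shape[0], BEAT_SAMPLES))
        for lead in range(values.shape[0]):
            beat[lead] = np.interp(tgt, xs, values[lead])
        beats.append(beat)
    return beats


def average_maps(beat_lists: list[list[np.ndarray]], class_label: str
                 ) -> AveragedAttentionMap:
    """Element-wise mean over all beats of all samples of one class."""
    all_beats = [b for beats in beat_lists for b in beats]
    if not all_beats:
        raise ValueError(f"no beats to average for class {class_label!r}")
    return AveragedAttentionMap(values=np.mean(all_beats, axis=0),
                                class_label=class_label,
                                n_samples=len([b for b in beat_lists if b]),
                                n_beats=len(all_beats))


def qrs_window_ratio(avg_map: AveragedAttentionMap, fs: float = 500.0,
                     window_ms: float = 60.0) -> float:
    """Mean heatmap value within +/-window_ms of the beat-grid R positions
    (samples 0 and 500) divided by the mean over the rest of the beat."""
    half = int(round(window_ms * 1e-3 * fs))
    v = avg_map.values
    mask = np.zeros(v.shape[1], dtype=bool)
    mask[:half] = True
    mask[-half:] = True
    qrs_mean = float(v[:, mask].mean())
    background = float(v[:, ~mask].mean())
    if background == 0:
        return np.inf if qrs_mean > 0 else 1.0
    return qrs_mean / background


# -------------------------------------------------------------------------
# cohort-level pipeline
# -------------------------------------------------------------------------

def class_averaged_map(net: LeadTokenNetwork, samples: list[TrajectorySample],
                       class_label: str, window: WindowSpec = WindowSpec(),
                       seed: int = 0, max_samples: int | None = None
                       ) -> AveragedAttentionMap:
    """Averaged fused heatmap on the RR-normalized beat grid for all samples
    of one true class: per sample, build a deterministic dual window, fuse
    attention with Grad-CAM, detect QRS separately in the baseline and
    follow-up halves (lead II), and RR-normalize each half with its own
    peaks.  The result is (24, 500)."""
    chosen = [s for s in samples if s.label.value == class_label]
    if max_samples is not None:
        chosen = chosen[:max_samples]
    if not chosen:
        raise ValueError(f"no samples with label {class_label!r}")
    rng = np.random.default_rng(seed)
    base_beats, follow_beats = [], []
    skipped = 0
    for s in chosen:
        b = extract_window(s.baseline.ecg, window, rng)
        f = extract_window(s.follow_up.ecg, window, rng)
        dual = concat_dual(b, f).astype(np.float32)
        heat = sample_heatmap(net, dual, target=s.class_index)
        try:
            pk_b = detect_qrs(b[1], window.fs)
            pk_f = detect_qrs(f[1], window.fs)
            base_beats.append(rr_normalize(heat.values[:12], pk_b, window.fs))
            follow_beats.append(rr_normalize(heat.values[12:], pk_f, window.fs))
        except ValueError:
            skipped += 1
    if skipped:
        logger.warning("skipped %d/%d samples with <2 detected beats",
                       skipped, len(chosen))
    if not base_beats:
        raise ValueError("QRS detection failed on every sample")
    avg_b = average_maps(base_beats, class_label)
    avg_f = average_maps(follow_beats, class_label)
    return AveragedAttentionMap(
        values=np.concatenate([avg_b.values, avg_f.values], axis=0),
        class_label=class_label,
        n_samples=len(base_beats),
        n_beats=avg_b.n_beats + avg_f.n_beats)


def plot_heatmap(window: np.ndarray, heatmap: AttentionHeatmap,
                 lead_names: list[str] | None = None, fs: float = 500.0):
    """Panel-per-lead figure with the ECG trace over the relevance map."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n_leads = window.shape[0]
    ncols = max(1, n_leads // 12)
    fig, axes = plt.subplots(12, ncols, figsize=(5 * ncols, 14),
                             sharex=True, squeeze=False)
    t = np.arange(window.shape[1]) / fs
    for lead in range(n_leads):
        ax = axes[lead % 12][lead // 12]
        ax.imshow(heatmap.values[lead][None, :], aspect="auto", cmap="Reds",
                  extent=(t[0], t[-1], window[lead].min(), window[lead].max()),
                  vmin=0, vmax=1, alpha=0.8)
        ax.plot(t, window[lead], lw=0.6, color="black")
        name = lead_names[lead] if lead_names else f"lead {lead}"
        ax.set_ylabel(name, fontsize=7)
    fig.tight_layout()
    return fig
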