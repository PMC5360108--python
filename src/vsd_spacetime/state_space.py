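"""State-space analyses of the derivative field.

Two complementary analyses live here.

**Spatial PCA.**  The channels x time fields of several conditions and
replicates are stacked into an observation matrix X (rows = time points,
columns = channels), each field centered on its own per-channel pre-stimulus
mean so the origin of state space is the pre-stimulus operating point, and
decomposed by SVD, X = U S V^T.  The 3-D trajectory of a condition is the
time-ordered first three columns of U S; with the reported variance
fractions s_k^2 / sum s^2 the first three components typically capture the
bulk of a stimulus-evoked field.  A divergence time between two conditions
is declared at the first post-stimulus moment their 3-D inter-trajectory
distance exceeds mean + k_sd * SD of its own pre-stimulus distribution and
stays above it for a sustained interval (defaults k_sd = 3, 20 ms) — an
explicit operationalization of "the trajectories diverged".

**Temporal condition difference.**  For a small zone (by default the 4
channels mapping the center of field of view) each replicate contributes one
mean time vector per condition.  The two conditions' vectors from all
replicates are pooled into one matrix; its first three principal component
time courses form a common temporal basis; each vector is projected onto the
basis (beta estimates) and reconstructed; the per-replicate difference of
the two reconstructions is tested against zero at every time point with a
one-sample t-test, and the time axis is corrected with Benjamini-Hochberg
FDR at 0.05.  Features outside the shared 3-D basis are removed before the
comparison, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAResult", "spatial_pca", "trajectory_coords", "divergence_time",
    "ConditionDifference", "temporal_condition_difference",
]


@dataclass
class PCAResult:
    """Full SVD of the stacked observation matrix.

    ``coords`` holds U S (observations in component space); ``components``
    the orthonormal spatial modes V (channels x components); ``index`` one
    row per observation with columns condition, replicate, time_index.
    """

    singular_values: np.ndarray
    components: np.ndarray
    coords: np.ndarray
    variance_fractions: np.ndarray
    index: pd.DataFrame
    channel_subset: np.ndarray

    def reconstruction(self) -> np.ndarray:
        """U S V^T — equals the centered input to machine precision."""
        return self.coords @ self.components.T


def _normalize_fields(fields) -> dict:
    out = {}
    for key, value in fields.items():
        if isinstance(key, tuple):
            cond, rep = key
        else:
            cond, rep = key, 0
        out[(cond, rep)] = np.asarray(value, dtype=float)
    return out


def spatial_pca(
    fields,
    onset_index: int | None = None,
    channel_subset=None,
) -> PCAResult:
    """SVD-based spatial PCA of stacked channels x time fields.

    ``fields`` maps ``condition`` or ``(condition, replicate)`` to a
    channels x time array; all must share both axes.  Each field is centered
    on its own per-channel pre-stimulus mean (samples before ``onset_index``)
    before stacking; with ``onset_index`` None the global per-channel mean is
    removed instead.  Component signs are fixed by making the
    largest-magnitude loading of each component positive.
    """
    fields = _normalize_fields(fields)
    shapes = {v.shape for v in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share the channels x time shape")
    n_channels, n_times = shapes.pop()
    if channel_subset is None:
        channel_subset = np.arange(n_channels)
    channel_subset = np.asarray(channel_subset, dtype=int)

    rows, records = [], []
    for (cond, rep), field in sorted(fields.items(), key=lambda kv: str(kv[0])):
        if not np.all(np.isfinite(field)):
            raise ValueError(f"field {(cond, rep)} contains non-finite values")
        sub = field[channel_subset]
        if onset_index is None:
            center = sub.mean(axis=1, keepdims=True)
        else:
            if onset_index < 1:
                raise ValueError("onset_index must leave a pre-stimulus period")
            center = sub[:, :onset_index].mean(axis=1, keepdims=True)
        rows.append((sub - center).T)  # times x channels
        records.extend(
            {"condition": cond, "replicate": rep, "time_index": t}
            for t in range(n_times)
        )
    x = np.vstack(rows)
    n, l = x.shape
    if n < l:
        import warnings

        warnings.warn(f"fewer observations ({n}) than channels ({l}); "
                      "the decomposition is still valid", stacklevel=2)

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    v = vt.T
    # sign convention: dominant loading of each component positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip[None, :]
    u = u * flip[None, :]

    var = s**2
    return PCAResult(
        singular_values=s,
        components=v,
        coords=u * s[None, :],
        variance_fractions=var / var.sum(),
        index=pd.DataFrame.from_records(records),
        channel_subset=channel_subset,
    )


def trajectory_coords(
    pca: PCAResult,
    condition,
    n_components: int = 3,
    average_replicates: bool = True,
) -> np.ndarray:
    """Time-ordered state-space coordinates of one condition.

    Returns a (times, n_components) array of U S coordinates.  With several
    replicates the coordinates are averaged over them unless
    ``average_replicates`` is False, in which case a
    (replicates, times, n_components) array comes back.
    """
    mask = (pca.index["condition"] == condition).to_numpy()
    if not mask.any():
        raise KeyError(f"condition {condition!r} not present in the PCA")
    idx = pca.index[mask]
    coords = pca.coords[mask, :n_components]
    reps = sorted(idx["replicate"].unique())
    per_rep = np.stack([
        coords[(idx["replicate"] == r).to_numpy()][
            np.argsort(idx.loc[idx["replicate"] == r, "time_index"].to_numpy())
        ]
        for r in reps
    ])
    return per_rep.mean(axis=0) if average_replicates else per_rep


def divergence_time(
    traj_a: np.ndarray,
    traj_b: np.ndarray,
    onset_index: int,
    sampling_rate_hz: float,
    k_sd: float = 3.0,
    sustain_ms: float = 20.0,
    min_prestim_samples: int = 100,
) -> float | None:
    """First sustained separation of two state-space trajectories, in ms.

    The inter-trajectory Euclidean distance d(t) is compared with the
    mean + k_sd * SD of its pre-stimulus distribution; the divergence time is
    the first post-stimulus time at which d(t) stays above that threshold
    continuously for ``sustain_ms``.  Returns None when the trajectories
    never diverge by that criterion.
    """
    traj_a = np.asarray(traj_a, dtype=float)
    traj_b = np.asarray(traj_b, dtype=float)
    if traj_a.shape != traj_b.shape:
        raise ValueError("trajectories must share shape")
    if onset_index < min_prestim_samples:
        raise ValueError(
            f"pre-stimulus window too short ({onset_index} samples; "
            f"need >= {min_prestim_samples})"
        )
    d = np.linalg.norm(traj_a - traj_b, axis=1)
    pre = d[:onset_index]
    threshold = pre.mean() + k_sd * pre.std(ddof=1)
    above = d[onset_index:] > threshold
    need = max(1, int(round(sustain_ms * sampling_rate_hz / 1000.0)))
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            start = i - need + 1
            return start * 1000.0 / sampling_rate_hz
    return None


@dataclass
class ConditionDifference:
    """Outcome of the temporal-domain two-condition comparison."""

    significant: np.ndarray     # boolean per time point
    p_values: np.ndarray        # BH-adjusted, per time point
    difference: np.ndarray      # replicates x time reconstruction differences
    betas: dict                 # (condition, replicate) -> (n_components,)
    components: np.ndarray      # time x n_components PC time courses


def temporal_condition_difference(
    zone_series: dict,
    fdr_level: float = 0.05,
    n_components: int = 3,
) -> ConditionDifference:
    """Test where two conditions' zone time courses differ, FDR over time.

    ``zone_series`` maps ``(condition, replicate)`` to a 1-D time vector
    (the zone-mean dVSD/dt of that replicate); exactly two conditions and at
    least 3 common replicates are required.
    """
    series = {k: np.asarray(v, dtype=float).ravel() for k, v in zone_series.items()}
    conds = sorted({c for c, _ in series})
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    reps = sorted({r for _, r in series})
    reps = [r for r in reps if all((c, r) in series for c in conds)]
    if len(reps) < 3:
        raise ValueError("need >= 3 replicates with both conditions")
    lengths = {series[(c, r)].shape[0] for c in conds for r in reps}
    if len(lengths) != 1:
        raise ValueError("all time vectors must share length")

    x = np.vstack([series[(c, r)] for c in conds for r in reps])
    xc = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    pcs = vt[:n_components].T  # time x components, orthonormal columns

    betas = {}
    recon = {}
    for c in conds:
        for r in reps:
            b = pcs.T @ series[(c, r)]
            betas[(c, r)] = b
            recon[(c, r)] = pcs @ b
    diff = np.vstack([recon[(conds[1], r)] - recon[(conds[0], r)] for r in reps])

    t_res = stats.ttest_1samp(diff, popmean=0.0, axis=0)
    p_adj = stats.false_discovery_control(t_res.pvalue, method="bh")
    return ConditionDifference(
        significant=p_adj <= fdr_level,
        p_values=p_adj,
        difference=diff,
        betas=betas,
        components=pcs,
    )
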