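"""PSM-to-protein quantification for isobaric (TMT) reporter-ion data.

Implements the quantification chain applied to 11-plex reporter intensities:
label-impurity correction, low-intensity PSM filtering, trimmed-median channel
normalization, PSM-to-protein summarization on the relative scale, and
internal-standard bridging across batches.

The chain is scale-equivariant: multiplying every raw intensity by ``c``
leaves relative intensities unchanged and shifts log2 absolute intensities by
``log2(c)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PSMTable:
    """PSM-level reporter intensities.

    ``df`` holds psm_id, protein_id, batch_id, jscore; ``intensities`` is the
    aligned n_psms x n_channels nonnegative matrix; ``channel_labels`` maps
    each batch to its ordered channel labels (sample ids + internal standard);
    ``is_channel`` is the internal-standard column index (last by default).
    """

    df: pd.DataFrame
    intensities: np.ndarray
    channel_labels: dict[str, list[str]] = field(default_factory=dict)
    is_channel: int = 10

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.df) != len(self.intensities):
            raise ValueError("metadata and intensity row counts differ")
        if self.intensities.size and self.intensities.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "PSMTable":
        return PSMTable(
            self.df.reset_index(drop=True).copy(),
            self.intensities.copy(),
            {k: list(v) for k, v in self.channel_labels.items()},
            self.is_channel,
        )

    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.df["batch_id"]))


@dataclass
class ImpurityMatrix:
    """Channel x channel label-spillover fractions.

    Column j gives the distribution of label j's signal over observed
    channels; columns sum to at most 1 and the diagonal dominates.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("impurity matrix must be square")
        if (M.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("impurity matrix columns must sum to <= 1")
        if (2 * np.diag(M) < np.abs(M).sum(axis=0)).any():
            raise ValueError("impurity matrix must be diagonally dominant per column")
        self.matrix = M

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def make_impurity(n_channels: int, spillover: float = 0.05) -> ImpurityMatrix:
    """Adjacent-channel spillover model: a fraction leaks to each neighbor."""
    M = np.eye(n_channels) * (1.0 - 2.0 * spillover)
    M[0, 0] = M[-1, -1] = 1.0 - spillover
    for j in range(n_channels):
        if j > 0:
            M[j - 1, j] = spillover
        if j < n_channels - 1:
            M[j + 1, j] = spillover
    return ImpurityMatrix(M)


# ---------------------------------------------------------------------------
# quantification steps
# ---------------------------------------------------------------------------

def correct_impurity(psm: PSMTable, M: ImpurityMatrix) -> PSMTable:
    """Invert the label-spillover mixing: solve M t = observed per PSM.

    Negative solutions (possible with noisy low intensities) are clipped to 0.
    """
    A = M.matrix if isinstance(M, ImpurityMatrix) else np.asarray(M, float)
    if np.linalg.matrix_rank(A) < A.shape[0]:
        raise np.linalg.LinAlgError("impurity matrix is singular; cannot correct")
    out = psm.copy()
    t = np.linalg.solve(A, out.intensities.T).T
    out.intensities = np.clip(t, 0.0, None)
    return out


def filter_psms(
    psm: PSMTable, min_intensity: float = 1000.0, median_intensity: float = 5000.0
) -> PSMTable:
    """Drop low-intensity PSMs.

    A PSM survives iff its per-channel minimum >= ``min_intensity`` AND its
    per-channel median >= ``median_intensity`` (boundaries inclusive).
    """
    mins = psm.intensities.min(axis=1)
    meds = np.median(psm.intensities, axis=1)
    keep = (mins >= min_intensity) & (meds >= median_intensity)
    if not keep.any():
        warnings.warn("all PSMs fall below the intensity filters; empty table returned")
    out = psm.copy()
    out.df = out.df.loc[keep].reset_index(drop=True)
    out.intensities = out.intensities[keep]
    return out


def _trimmed_channel_medians(x: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Per-channel medians over PSMs retained after trimming the top and
    bottom ``trim_fraction`` of PSMs by overall (row-mean) intensity."""
    n = len(x)
    k = int(np.floor(trim_fraction * n))
    if n - 2 * k < 10:
        if n >= 10:
            k = max(0, (n - 10) // 2)
        else:
            warnings.warn("fewer than 10 PSMs; falling back to untrimmed median")
            k = 0
    order = np.argsort(x.mean(axis=1), kind="stable")
    kept = order[k : n - k] if k else order
    return np.median(x[kept], axis=0)


def normalize_channels(
    psm: PSMTable, trim_fraction: float = 0.1, tol: float = 1e-12, max_iter: int = 50
) -> PSMTable:
    """Equalize per-channel trimmed-median PSM intensity within each batch.

    Each channel is rescaled so that its trimmed median matches the batch
    grand trimmed median (median of the per-channel values).  Because the
    trim set depends on overall PSM intensity, which itself moves under
    rescaling, the scaling is iterated to a fixed point; it converges in a
    handful of iterations and leaves post-normalization trimmed medians
    equal across channels to numerical precision.
    """
    out = psm.copy()
    for batch in out.batches():
        idx = (out.df["batch_id"] == batch).to_numpy()
        x = out.intensities[idx]
        if len(x) == 0:
            continue
        for _ in range(max_iter):
            med = _trimmed_channel_medians(x, trim_fraction)
            if (med <= 0).any():
                raise ValueError(f"nonpositive channel median in batch {batch}")
            grand = np.median(med)
            factors = grand / med
            x = x * factors[None, :]
            if np.max(np.abs(factors - 1.0)) < tol:
                break
        out.intensities[idx] = x
    return out


def summarize_proteins(psm: PSMTable, batch: str | None = None) -> pd.DataFrame:
    """Collapse PSMs to one protein x channel matrix of log2 intensities.

    Per PSM the relative intensity is channel / row-mean; per protein the
    relative profile is the mean over its PSMs, and the absolute level is
    that profile times the grand mean of the protein's three most intense
    PSMs (all PSMs when fewer than three).  Output is log2-transformed with
    an ``n_psm`` column appended.
    """
    out_rows = {}
    df = psm.df.reset_index(drop=True)
    if batch is not None:
        sel = (df["batch_id"] == batch).to_numpy()
        df = df.loc[sel].reset_index(drop=True)
        inten = psm.intensities[sel]
    else:
        inten = psm.intensities
    for prot, grp in df.groupby("protein_id", sort=True):
        rows = inten[grp.index.to_numpy()]
        rows = rows[rows.sum(axis=1) > 0]
        if len(rows) == 0:
            logger.info("protein %s has no surviving PSMs; omitted", prot)
            continue
        rel = rows / rows.mean(axis=1, keepdims=True)
        rel_prot = rel.mean(axis=0)
        order = np.argsort(rows.mean(axis=1))[::-1]
        top = rows[order[: min(3, len(rows))]]
        grand = top.mean()
        out_rows[prot] = np.concatenate([np.log2(rel_prot * grand), [len(rows)]])
    cols = list(range(psm.n_channels)) + ["n_psm"]
    out = pd.DataFrame.from_dict(out_rows, orient="index", columns=cols)
    out.index.name = "protein_id"
    return out


def bridge_batches(
    per_batch: dict[str, pd.DataFrame],
    channel_labels: dict[str, list[str]],
    is_label: str = "IS",
) -> pd.DataFrame:
    """Combine per-batch protein matrices via the internal-standard channel.

    Each sample channel's log2 intensity is centered on its batch's
    internal standard; batches are then concatenated over the union of
    proteins, leaving a protein missing (NaN) for the samples of any batch
    in which it was not quantified.
    """
    pieces = []
    for batch, mat in per_batch.items():
        labels = channel_labels[batch]
        if is_label not in labels:
            raise ValueError(f"batch {batch} lacks an internal-standard channel {is_label!r}")
        is_idx = labels.index(is_label)
        chan_cols = [c for c in mat.columns if c != "n_psm"]
        vals = mat[chan_cols].to_numpy()
        centered = vals - vals[:, [is_idx]]
        keep = [i for i in range(len(labels)) if i != is_idx]
        piece = pd.DataFrame(centered[:, keep], index=mat.index, columns=[labels[i] for i in keep])
        pieces.append(piece)
    combined = pd.concat(pieces, axis=1)
    combined.index.name = "protein_id"
    return combined


def quantify(
    psm: PSMTable,
    impurity: ImpurityMatrix | None = None,
    min_intensity: float = 1000.0,
    median_intensity: float = 5000.0,
    trim_fraction: float = 0.1,
) -> pd.DataFrame:
    """Full chain: impurity-correct, filter, normalize, summarize, bridge.

    Returns the proteins x samples matrix of internal-standard-centered
    log2 intensities.
    """
    step = correct_impurity(psm, impurity) if impurity is not None else psm
    step = filter_psms(step, min_intensity, median_intensity)
    step = normalize_channels(step, trim_fraction)
    per_batch = {b: summarize_proteins(step, batch=b) for b in step.batches()}
    return bridge_batches(per_batch, step.channel_labels)
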