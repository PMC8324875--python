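"""Windowed read-depth copy-number analysis of the locus.

Reads are counted into non-overlapping windows (default 5 kb) by start
position, normalised to the mean count over informative (mask-filtered)
windows, corrected by ratio to a full-complement control strain, and
segmented into deletions; per-gene copy state (0/1/2) is called from the
median control ratio over the windows overlapping each gene.

The ratio-to-control step absorbs mappability structure: raw normalised
depth is not uniform along a repeat-dense contig, but it is reproducible
across strains carrying the full gene complement, so the test/control
ratio is ~1 where two copies are present, ~0.5 over heterozygous
deletions, and ~0 over homozygous deletions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locus_io import GeneModel, ParalogueLocus

__all__ = [
    "DepthProfile",
    "DeletionSegment",
    "CopyCall",
    "window_masked_fraction",
    "count_windows",
    "normalise_profile",
    "ratio_to_control",
    "segment_deletions",
    "call_gene_copies",
    "profile_table",
    "deletion_bed",
    "copy_calls_table",
    "plot_depth_track",
]

STATUS_BY_COPIES = {0: "absent", 1: "het-deletion", 2: "present"}


def placements_from_alignment(path: str | Path,
                              contig: str | None = None) -> pd.DataFrame:
    """Adapter: read start positions from a SAM/BAM/CRAM file.

    Records are filtered to mapped, primary, non-duplicate, non-qcfail
    reads; the returned frame matches the placement-table schema.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path)) as af:
        for rec in af:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.is_duplicate or rec.is_qcfail):
                continue
            if contig is not None and rec.reference_name != contig:
                continue
            rows.append((rec.query_name, rec.reference_name,
                         rec.reference_start, rec.reference_end or
                         rec.reference_start + rec.query_length, 0))
    return pd.DataFrame(
        rows, columns=["read_id", "contig", "start", "end", "haplotype"]
    )


@dataclass
class DepthProfile:
    strain_id: str
    window_size: int
    counts: np.ndarray  # reads whose start falls in each window
    masked_fraction: np.ndarray
    contig_len: int
    normalised: np.ndarray | None = None
    included: np.ndarray | None = None  # informative windows (mask filter)
    errors: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.counts)


@dataclass
class DeletionSegment:
    start_window: int
    end_window: int  # inclusive
    start_bp: int
    end_bp: int
    mean_ratio: float


@dataclass
class CopyCall:
    gene_id: str
    copies: int | None  # None when ambiguous
    mean_ratio: float
    status: str  # present | het-deletion | absent | ambiguous
    n_windows: int


def window_masked_fraction(contig_len: int, masked: list[tuple[int, int]],
                           window_size: int) -> np.ndarray:
    """Fraction of each window covered by mask intervals (last window may
    be partial; its fraction is relative to its actual width)."""
    n = math.ceil(contig_len / window_size)
    cov = np.zeros(n)
    for s, e in masked:
        w0, w1 = s // window_size, (e - 1) // window_size
        for w in range(w0, w1 + 1):
            ws, we = w * window_size, min((w + 1) * window_size, contig_len)
            cov[w] += max(0, min(e, we) - max(s, ws))
    widths = np.minimum(
        np.arange(1, n + 1) * window_size, contig_len
    ) - np.arange(n) * window_size
    return cov / widths


def count_windows(placements: pd.DataFrame | np.ndarray, contig_len: int,
                  window_size: int = 5000, strain_id: str = "",
                  masked_fraction: np.ndarray | None = None) -> DepthProfile:
    """Count reads per window by start position (one window per read).

    Out-of-contig placements are collected into the profile's error list
    rather than raising.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    starts = (placements["start"].to_numpy()
              if isinstance(placements, pd.DataFrame) else np.asarray(placements))
    n = math.ceil(contig_len / window_size)
    ok = (starts >= 0) & (starts < contig_len)
    errors = [f"placement start {int(s)} outside contig [0, {contig_len})"
              for s in starts[~ok]]
    counts = np.bincount(starts[ok] // window_size, minlength=n).astype(int)
    if masked_fraction is None:
        masked_fraction = np.zeros(n)
    return DepthProfile(strain_id, window_size, counts,
                        np.asarray(masked_fraction, dtype=float),
                        contig_len, errors=errors)


def normalise_profile(profile: DepthProfile,
                      mask_threshold: float = 0.9) -> DepthProfile:
    """Normalise counts to the mean over informative windows.

    Windows with masked fraction above ``mask_threshold`` are excluded
    from the mean and flagged; included normalised values average to 1.
    Idempotent on its own output (the normalised track is rescaled by its
    own included mean, which is already 1).
    """
    included = profile.masked_fraction <= mask_threshold
    if not included.any():
        raise ValueError("no informative windows to normalise against")
    base = (profile.normalised if profile.normalised is not None
            else profile.counts.astype(float))
    mean = base[included].mean()
    if mean == 0:
        raise ValueError("mean count over informative windows is zero")
    return DepthProfile(
        profile.strain_id, profile.window_size, profile.counts,
        profile.masked_fraction, profile.contig_len,
        normalised=base / mean, included=included, errors=list(profile.errors),
    )


def ratio_to_control(profile: DepthProfile, control: DepthProfile,
                     floor: float = 0.1) -> np.ndarray:
    """Per-window test/control ratio of normalised depths.

    Windows where the control's normalised depth is below ``floor``, or
    that are mask-excluded in either profile, are uninformative (NaN).
    """
    if (profile.window_size != control.window_size
            or profile.n_windows != control.n_windows):
        raise ValueError("window grids differ between test and control")
    if profile.normalised is None or control.normalised is None:
        raise ValueError("profiles must be normalised first")
    ratio = np.full(profile.n_windows, np.nan)
    ok = (profile.included & control.included
          & (control.normalised >= floor))
    ratio[ok] = profile.normalised[ok] / control.normalised[ok]
    return ratio


def segment_deletions(ratio: np.ndarray, window_size: int = 5000,
                      low: float = 0.25,
                      min_windows: int = 2) -> list[DeletionSegment]:
    """Maximal runs of >= min_windows informative windows with ratio < low.

    Uninformative (NaN) windows do not break a run but do not count
    toward its length.
    """
    segments: list[DeletionSegment] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_windows:
            vals = ratio[run]
            segments.append(DeletionSegment(
                start_window=run[0], end_window=run[-1],
                start_bp=run[0] * window_size,
                end_bp=(run[-1] + 1) * window_size,
                mean_ratio=float(np.mean(vals)),
            ))
        run.clear()

    for w, r in enumerate(ratio):
        if np.isnan(r):
            continue
        if r < low:
            run.append(w)
        else:
            flush()
    flush()
    return segments


def call_gene_copies(ratio: np.ndarray, genes: dict[str, GeneModel] | ParalogueLocus,
                     window_size: int = 5000,
                     thresholds: tuple[float, float] = (0.25, 0.75),
                     gain_flag: float = 1.5) -> list[CopyCall]:
    """Per-gene copy state from the median ratio over overlapping windows.

    median < thresholds[0] -> 0 copies (absent); < thresholds[1] -> 1
    (het-deletion); otherwise 2 (present).  Fewer than 2 informative
    overlapping windows -> ambiguous.  A median above ``gain_flag`` keeps
    status ``present`` but is reported in the table as a putative gain.
    """
    if isinstance(genes, ParalogueLocus):
        genes = genes.genes
    lo, hi = thresholds
    calls = []
    for gid, gene in genes.items():
        s, e = gene.span
        w0, w1 = s // window_size, (e - 1) // window_size
        vals = ratio[w0:w1 + 1]
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            calls.append(CopyCall(gid, None, float("nan"), "ambiguous", len(vals)))
            continue
        med = float(np.median(vals))
        copies = 0 if med < lo else (1 if med < hi else 2)
        calls.append(CopyCall(gid, copies, med, STATUS_BY_COPIES[copies],
                              len(vals)))
    return calls


# ---------------------------------------------------------------------------
# Tabular / graphical output
# ---------------------------------------------------------------------------

def profile_table(profile: DepthProfile,
                  ratio: np.ndarray | None = None) -> pd.DataFrame:
    df = pd.DataFrame({
        "window": np.arange(profile.n_windows),
        "start": np.arange(profile.n_windows) * profile.window_size,
        "count": profile.counts,
        "masked_fraction": profile.masked_fraction,
    })
    if profile.normalised is not None:
        df["normalised"] = profile.normalised
        df["informative"] = profile.included
    if ratio is not None:
        df["ratio"] = ratio
    return df


def deletion_bed(segments: list[DeletionSegment], contig: str) -> str:
    return "".join(
        f"{contig}\t{s.start_bp}\t{s.end_bp}\tdeletion\t{s.mean_ratio:.4f}\n"
        for s in segments
    )


def copy_calls_table(calls: list[CopyCall], gain_flag: float = 1.5) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene_id": c.gene_id,
            "copies": c.copies,
            "status": c.status,
            "mean_ratio": c.mean_ratio,
            "n_windows": c.n_windows,
            "putative_gain": (c.copies == 2 and c.mean_ratio > gain_flag),
        }
        for c in calls
    ])


def plot_depth_track(profile: DepthProfile, path: str | Path,
                     ratio: np.ndarray | None = None,
                     genes: dict[str, GeneModel] | None = None) -> None:
    """Normalised depth per window, the standard CNV-visualisation track."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = (np.arange(profile.n_windows) + 0.5) * profile.window_size / 1000
    fig, ax = plt.subplots(figsize=(10, 3))
    if profile.normalised is not None:
        ax.plot(x, profile.normalised, ".", ms=3, label="normalised depth")
    if ratio is not None:
        ax.plot(x, ratio, "-", lw=0.8, alpha=0.7, label="ratio to control")
    if genes:
        for g in genes.values():
            s, e = g.span
            ax.axvspan(s / 1000, e / 1000, color="0.85", zorder=0)
    ax.set_xlabel("contig position (kb)")
    ax.set_ylabel("relative depth")
    ax.set_title(profile.strain_id)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
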