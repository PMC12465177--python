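"""Depth-of-coverage karyotype scanning.

Windowed read counts are normalized against a trimmed autosomal mean, with
sex-aware expected ratios per chromosome class (autosome 1.0; X 0.5 in
males, 1.0 in females; Y 0.5 in males, 0.0 in females). Whole-chromosome
calls compare the median normalized ratio against 0.5x/1.0x/1.5x bands;
chromosomes that fit none of the bands are scanned for a single terminal
changepoint (the published partial-monosomy event is chromosome-terminal;
interior segments are visible in the export table but not called).

No GC or mappability correction is applied: the robust trimmed mean is the
only normalization, matching the plain read-count input the scan consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .io import CoverageWindow, GenomicInterval

__all__ = [
    "PloidyModel",
    "AneuploidyCall",
    "CnvConfig",
    "normalize",
    "call_chromosome",
    "detect_terminal_segment",
    "genome_scan",
]


@dataclass(frozen=True)
class PloidyModel:
    """Expected normalized coverage ratio per chromosome class for a sex."""

    sex: str  # male | female
    #: chromosome name -> class ("autosome" | "X" | "Y")
    chrom_classes: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")

    def chrom_class(self, chrom: str) -> str:
        if chrom in self.chrom_classes:
            return self.chrom_classes[chrom]
        if chrom in ("X", "chrX", "ChrX"):
            return "X"
        if chrom in ("Y", "chrY", "ChrY"):
            return "Y"
        return "autosome"

    def expected_ratio(self, chrom: str) -> float:
        cls = self.chrom_class(chrom)
        if cls == "autosome":
            return 1.0
        if cls == "X":
            return 0.5 if self.sex == "male" else 1.0
        return 0.5 if self.sex == "male" else 0.0


@dataclass(frozen=True)
class CnvConfig:
    delta: float = 0.15  # ratio tolerance around the 0.5/1.0/1.5 bands
    min_windows: int = 10  # minimum supporting windows for any call
    #: reference statistic for the autosomal rate: the median tolerates a
    #: whole aberrant chromosome (up to half the windows), which a small
    #: trimmed mean cannot on a compact genome model
    reference: str = "median"  # median | trimmed_mean
    trim: float = 0.01  # per-tail trim fraction for reference="trimmed_mean"
    min_autosomal_windows: int = 100


@dataclass
class AneuploidyCall:
    chrom: str
    call: str  # disomy | trisomy | monosomy | partial_monosomy | partial_gain | no_call
    median_ratio: float
    n_windows: int
    segment: GenomicInterval | None = None
    distance_from_end: int | None = None

    def __post_init__(self) -> None:
        partial = self.call in ("partial_monosomy", "partial_gain")
        if partial and self.segment is None:
            raise ValueError("partial events must carry a segment")
        if not partial and self.segment is not None:
            raise ValueError("whole-chromosome calls carry no segment")


def normalize(
    windows: list[CoverageWindow], model: PloidyModel, config: CnvConfig = CnvConfig()
) -> list[CoverageWindow]:
    """Fill per-window ratios: per-bp count rate / robust autosomal rate.

    The reference is the median autosomal rate by default (robust to a
    whole aberrant chromosome); a light trimmed mean is available via the
    config. Partial terminal windows are rated per-bp so their ratios stay
    comparable, but are excluded from the reference.
    """
    rates = np.array([w.count / w.width for w in windows], dtype=float)
    autosomal = np.array(
        [
            w.count / w.width
            for w in windows
            if model.chrom_class(w.interval.chrom) == "autosome" and not w.partial
        ]
    )
    if autosomal.size < config.min_autosomal_windows:
        raise ValueError(
            f"need >= {config.min_autosomal_windows} full autosomal windows, "
            f"got {autosomal.size}"
        )
    if config.reference == "median":
        mean = float(np.median(autosomal))
    elif config.reference == "trimmed_mean":
        mean = float(trim_mean(autosomal, config.trim))
    else:
        raise ValueError(f"unknown reference statistic {config.reference!r}")
    if mean == 0:
        raise ValueError("all-zero autosomal counts; cannot normalize")
    out = []
    for w, rate in zip(windows, rates):
        out.append(
            CoverageWindow(
                interval=w.interval, count=w.count, ratio=float(rate / mean), partial=w.partial
            )
        )
    return out


def _require_normalized(windows: list[CoverageWindow]) -> np.ndarray:
    ratios = np.array([w.ratio if w.ratio is not None else np.nan for w in windows])
    if np.isnan(ratios).any():
        raise ValueError("windows are not normalized; call normalize() first")
    return ratios


def call_chromosome(
    windows: list[CoverageWindow], model: PloidyModel, config: CnvConfig = CnvConfig()
) -> AneuploidyCall:
    """Whole-chromosome ploidy call from the median normalized ratio."""
    if not windows:
        raise ValueError("no windows for chromosome")
    chrom = windows[0].interval.chrom
    ratios = _require_normalized(windows)
    median = float(np.median(ratios))
    if len(windows) < config.min_windows:
        return AneuploidyCall(chrom, "no_call", median, len(windows))
    expected = model.expected_ratio(chrom)
    if expected == 0.0:
        # female Y: nothing to call
        return AneuploidyCall(chrom, "no_call", median, len(windows))
    m = median / expected
    d = config.delta
    if 1.0 - d <= m <= 1.0 + d:
        return AneuploidyCall(chrom, "disomy", median, len(windows))
    if 1.5 - d <= m <= 1.5 + d:
        return AneuploidyCall(chrom, "trisomy", median, len(windows))
    if 0.5 - d <= m <= 0.5 + d:
        return AneuploidyCall(chrom, "monosomy", median, len(windows))
    return AneuploidyCall(chrom, "no_call", median, len(windows))


def _terminal_sse(ratios: np.ndarray, expected: float, level: float) -> tuple[int, float, bool]:
    """Best single terminal changepoint under a two-level model.

    Fits `expected` on the body and `level * expected` on a terminal
    segment, scanning both chromosome ends with prefix sums (O(n)).
    Returns (breakpoint index counted over the oriented array, SSE,
    from_right) for the better end.
    """
    n = ratios.size
    best = (0, np.inf, False)
    for from_right in (False, True):
        r = ratios[::-1] if from_right else ratios
        seg_prefix = np.cumsum((r - level * expected) ** 2)
        body_suffix = np.concatenate(
            [np.cumsum(((r - expected) ** 2)[::-1])[::-1], [0.0]]
        )
        # breakpoint b: windows [0, b) are the terminal segment, [b, n) the body
        sse = seg_prefix[: n - 1] + body_suffix[1:n]
        b = int(np.argmin(sse)) + 1
        if sse[b - 1] < best[1]:
            best = (b, float(sse[b - 1]), from_right)
    return best


def detect_terminal_segment(
    windows: list[CoverageWindow], model: PloidyModel, config: CnvConfig = CnvConfig()
) -> AneuploidyCall:
    """Single-changepoint scan for a terminal half-ploidy loss (or gain).

    Chooses the breakpoint minimizing the squared error of a two-level
    model (expected ratio on the body, 0.5x or 1.5x on the terminal
    segment). A call requires the terminal segment to span at least
    ``min_windows`` windows with mean ratio within ``delta`` of its level
    and the body within ``delta`` of expectation; otherwise no_call.
    """
    if not windows:
        raise ValueError("no windows for chromosome")
    chrom = windows[0].interval.chrom
    ws = sorted(windows, key=lambda w: w.interval.start)
    ratios = _require_normalized(ws)
    median = float(np.median(ratios))
    n = ratios.size
    expected = model.expected_ratio(chrom)
    if expected == 0.0 or n < 2 * config.min_windows:
        return AneuploidyCall(chrom, "no_call", median, n)
    best_call = None
    best_sse = np.inf
    for level, name in ((0.5, "partial_monosomy"), (1.5, "partial_gain")):
        b, sse, from_right = _terminal_sse(ratios, expected, level)
        if sse >= best_sse:
            continue
        r = ratios[::-1] if from_right else ratios
        seg_mean = float(r[:b].mean())
        body_mean = float(r[b:].mean())
        if b < config.min_windows:
            continue
        if abs(seg_mean - level * expected) > config.delta * expected:
            continue
        if abs(body_mean - expected) > config.delta * expected:
            continue
        if from_right:
            seg_windows = ws[n - b :]
        else:
            seg_windows = ws[:b]
        segment = GenomicInterval(
            chrom, seg_windows[0].interval.start, seg_windows[-1].interval.end
        )
        best_sse = sse
        best_call = AneuploidyCall(
            chrom,
            name,
            median,
            n,
            segment=segment,
            distance_from_end=segment.length,
        )
    if best_call is None:
        return AneuploidyCall(chrom, "no_call", median, n)
    return best_call


def genome_scan(
    windows: list[CoverageWindow], model: PloidyModel, config: CnvConfig = CnvConfig()
) -> tuple[list[AneuploidyCall], pd.DataFrame]:
    """Per-chromosome calls plus a Manhattan-style export table.

    Windows must already be normalized. Chromosomes whose whole-chromosome
    call is ``no_call`` (with enough windows) are handed to the terminal
    changepoint scan.
    """
    by_chrom: dict[str, list[CoverageWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.interval.chrom, []).append(w)
    calls = []
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.interval.start)
        call = call_chromosome(ws, model, config)
        if call.call == "no_call" and len(ws) >= config.min_windows:
            partial = detect_terminal_segment(ws, model, config)
            if partial.call != "no_call":
                call = partial
        calls.append(call)
    export = pd.DataFrame(
        {
            "chrom": [w.interval.chrom for w in windows],
            "start": [w.interval.start for w in windows],
            "ratio": [w.ratio for w in windows],
        }
    )
    return calls, export
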