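"""Alignment conservation profiles and skew-content regressions.

``column_profile`` turns an alignment of junction or spacer windows
into the numeric content of a sequence logo: per-column base
frequencies and information content in bits,

    IC = 2 - H,   H = -sum f_b log2 f_b,

so a monomorphic column scores 2 bits and a uniform one scores 0.
``consensus_motif`` reads a majority-rule consensus off the profile,
masking sub-threshold columns with N.

``ols_fit`` / ``skew_content_regression`` fit the plain least-squares
line y = a + bx used to relate strand skew to base content across a
panel of genomes (e.g. AT-skew against A+T%), where comparative
mitogenomics typically finds negative slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .composition import region_summary
from .model import MitocompError, Mitogenome

__all__ = [
    "LogoMatrix",
    "RegressionFit",
    "column_profile",
    "consensus_motif",
    "ols_fit",
    "skew_content_regression",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column base frequencies and information content of an
    alignment."""

    columns: tuple[dict[str, float] | None, ...]
    info_bits: tuple[float, ...]
    n_sequences: int

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class RegressionFit:
    """Simple least-squares line fit."""

    slope: float
    intercept: float
    r_squared: float | None
    n: int
    stderr: float | None = None


def column_profile(alignment: list[str], *, small_sample_correction: bool = False) -> LogoMatrix:
    """Column frequencies and information content of an alignment.

    Gaps ('-') and N are excluded from column counts; an all-gap column
    has missing frequencies and 0 bits.  ``small_sample_correction``
    subtracts the standard e(n) = 3 / (2 ln2 n) bias term.
    """
    if not alignment:
        raise MitocompError("empty alignment")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise MitocompError(f"aligned sequences differ in length: {sorted(lengths)}")
    n_seq = len(alignment)
    columns: list[dict[str, float] | None] = []
    info: list[float] = []
    for i in range(next(iter(lengths))):
        col = [s[i].upper() for s in alignment]
        counted = [b for b in col if b in _BASES]
        if not counted:
            columns.append(None)
            info.append(0.0)
            continue
        total = len(counted)
        freqs = {b: counted.count(b) / total for b in _BASES}
        h = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        ic = 2.0 - h
        if small_sample_correction:
            ic -= 3.0 / (2.0 * math.log(2) * total)
        columns.append(freqs)
        info.append(max(0.0, ic))
    return LogoMatrix(tuple(columns), tuple(info), n_seq)


def consensus_motif(profile: LogoMatrix, threshold: float = 0.9) -> str:
    """Majority-rule consensus: the modal base where its frequency
    reaches ``threshold``, else N."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    out = []
    for col in profile.columns:
        if col is None:
            out.append("N")
            continue
        base, freq = max(col.items(), key=lambda kv: kv[1])
        out.append(base if freq >= threshold else "N")
    return "".join(out)


def ols_fit(points: list[tuple[float, float]]) -> RegressionFit:
    """Unweighted least-squares fit of y on x.

    Requires >= 2 points with non-constant x; r_squared is missing when
    y is constant (zero total sum of squares).
    """
    if len(points) < 2:
        raise MitocompError("ols_fit needs at least 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise MitocompError("degenerate fit: x values are all equal")
    res = stats.linregress(x, y)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = None if sst == 0 else float(res.rvalue**2)
    return RegressionFit(float(res.slope), float(res.intercept), r2, len(points),
                         float(res.stderr))


def skew_content_regression(genomes: list[Mitogenome], region: str,
                            axis: str = "AT", strand_mode: str = "coding") -> RegressionFit:
    """Regress strand skew on base content across a genome panel.

    x is the region's A+T% (axis "AT") or G+C% (axis "GC") per genome,
    y the corresponding skew.
    """
    if axis not in ("AT", "GC"):
        raise ValueError("axis must be 'AT' or 'GC'")
    if len(genomes) < 3:
        raise MitocompError("regression needs at least 3 genomes")
    points = []
    for g in genomes:
        s = region_summary(g, region, strand_mode)
        if axis == "AT":
            if s.at_skew is None:
                continue
            points.append((s.at_pct, s.at_skew))
        else:
            if s.gc_skew is None:
                continue
            points.append((s.gc_pct, s.gc_skew))
    return ols_fit(points)
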