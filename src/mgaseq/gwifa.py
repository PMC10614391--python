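"""Genome-wide interaction fluctuation analysis (GWIFA).

Discriminates the two physical forms of focal oncogene amplification —
extrachromosomal DNA (ecDNA) and intrachromosomal homogeneously staining
regions (HSR) — from how the amplicon's contacts fluctuate across the
genome. ecDNA moves freely through the nucleus and touches every
chromosome, so its contact fluctuation is spread genome-wide; an HSR sits
at one insertion locus, so nearly all of its fluctuation is concentrated
there.

The statistic chains four steps over the amplicon's per-bin contact
profile C_1..C_n (masked bins removed, genome order kept):

1. cumulative interaction intensity  CII_x = sum_{i<=x} C_i
2. second-order backward difference with spacing h
       SOBDc_x = (sum_{i=x-h+1..x} C_i - sum_{j=x-2h+1..x-h} C_j) / h^2
   defined for x in [2h, n]; algebraically
   (CII_x - 2*CII_{x-h} + CII_{x-2h}) / h^2.
3. fluctuation score: with S the descending-sorted |SOBDc| and k the top
   fraction (default 1/10) of its n values,
       FS = (S_1 + ... + S_k) / (S_1 + ... + S_n)
4. discrimination: ecDNA if FS < T, HSR if FS > T (T in (0, 1)).

FS is scale-free (invariant to multiplying all counts by a positive
constant) and immune to a constant offset per bin, which a linear trend in
CII represents; the optional detrended CII is diagnostic output only.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .contacts import ContactMatrix, ContactProfile, region_profile
from .genome import Region

ECDNA = "ecDNA"
HSR = "HSR"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class GwifaConfig:
    """Parameters of the fluctuation analysis.

    h: backward-difference spacing in bins (>= 1).
    top_fraction: fraction of the largest |SOBDc| values summed in the FS
        numerator; k = ceil(top_fraction * n) so k >= 1.
    T: discrimination threshold on FS, in (0, 1).
    detrend: also report the linear-fit residual of CII (diagnostic; FS is
        provably unaffected by a linear CII trend).
    trans_only: mask the query's whole chromosome, not just query bins, so
        the profile is purely inter-chromosomal.
    """

    h: int = 3
    top_fraction: float = 0.1
    T: float = 0.5
    detrend: bool = True
    trans_only: bool = True

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")
        if not (0 < self.top_fraction <= 1):
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if not (0 < self.T < 1):
            raise ValueError(f"T must be in (0, 1), got {self.T}")


@dataclass(frozen=True)
class Sobd:
    """A second-order backward difference vector with its index range.

    ``values[k]`` is SOBDc at x = first_x + k, where x is the 1-based index
    into the retained (unmasked) bin sequence and first_x = 2h.
    """

    values: np.ndarray
    h: int
    first_x: int


def _as_counts(profile: Union[ContactProfile, np.ndarray]) -> np.ndarray:
    if isinstance(profile, ContactProfile):
        counts = profile.unmasked_values()
    else:
        counts = np.asarray(profile, dtype=float)
    if counts.size == 0:
        raise ValueError("empty profile")
    if (counts < 0).any():
        raise ValueError("negative contact count in profile")
    return counts


def compute_cii(profile: Union[ContactProfile, np.ndarray]) -> np.ndarray:
    """Cumulative interaction intensity: prefix sums of the retained counts."""
    return np.cumsum(_as_counts(profile))


def detrend_cii(cii: np.ndarray) -> np.ndarray:
    """Residuals of an ordinary-least-squares line fitted to CII over x = 1..n."""
    cii = np.asarray(cii, dtype=float)
    if cii.size < 2:
        raise ValueError("need at least 2 CII values to detrend")
    x = np.arange(1, cii.size + 1, dtype=float)
    slope, intercept = np.polyfit(x, cii, 1)
    return cii - (slope * x + intercept)


def compute_sobd(counts: Union[ContactProfile, np.ndarray], h: int = 3) -> Sobd:
    """Second-order backward difference of the cumulative curve, spacing h.

    Requires n >= 2h retained bins; defined for x in [2h, n].
    """
    c = _as_counts(counts)
    n = c.size
    if h < 1:
        raise ValueError(f"h must be >= 1, got {h}")
    if n < 2 * h:
        raise ValueError(f"profile shorter than 2h bins (n={n}, h={h})")
    cii = np.concatenate(([0.0], np.cumsum(c)))
    x = np.arange(2 * h, n + 1)
    vals = (cii[x] - 2.0 * cii[x - h] + cii[x - 2 * h]) / (h * h)
    return Sobd(vals, h, 2 * h)


def fluctuation_score(
    sobd: Union[Sobd, np.ndarray], top_fraction: float = 0.1
) -> float:
    """Share of total |SOBDc| magnitude carried by the top fraction of values.

    FS is in (0, 1]: near 1 when fluctuation is concentrated at few loci
    (HSR-like), near top_fraction when spread evenly (ecDNA-like). Raises on
    an all-zero SOBD vector, for which the ratio is undefined.
    """
    v = sobd.values if isinstance(sobd, Sobd) else np.asarray(sobd, dtype=float)
    if v.size == 0:
        raise ValueError("empty SOBD vector")
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    s = np.sort(np.abs(v))[::-1]
    total = s.sum()
    if total == 0:
        raise ValueError("degenerate profile: no fluctuation")
    k = math.ceil(top_fraction * s.size)
    return float(s[:k].sum() / total)


def classify(fs: float, T: float = 0.5) -> str:
    """ecDNA if FS < T, HSR if FS > T; FS == T is reported as ambiguous."""
    if not (0 < fs <= 1):
        raise ValueError(f"FS must be in (0, 1], got {fs}")
    if not (0 < T < 1):
        raise ValueError(f"T must be in (0, 1), got {T}")
    if fs < T:
        return ECDNA
    if fs > T:
        return HSR
    return AMBIGUOUS


@dataclass
class GwifaResult:
    """Full output of one fluctuation analysis on one amplified region."""

    query: Region
    cii: np.ndarray
    sobd: Sobd
    fs: float
    call: str
    config: GwifaConfig
    n: int
    cii_detrended: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "query": self.query.label,
            "fs": self.fs,
            "call": self.call,
            "n_bins": self.n,
            "config": {
                "h": self.config.h,
                "top_fraction": self.config.top_fraction,
                "T": self.config.T,
                "trans_only": self.config.trans_only,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def run_gwifa(
    matrix: ContactMatrix,
    query: Region,
    config: GwifaConfig | None = None,
) -> GwifaResult:
    """Run the full analysis chain on one focal-amplification region.

    profile -> CII -> SOBD -> FS -> ecDNA/HSR call.
    """
    cfg = config or GwifaConfig()
    profile = region_profile(matrix, query, trans_only=cfg.trans_only)
    counts = _as_counts(profile)
    cii = np.cumsum(counts)
    sobd = compute_sobd(counts, cfg.h)
    fs = fluctuation_score(sobd, cfg.top_fraction)
    call = classify(fs, cfg.T)
    detrended = detrend_cii(cii) if cfg.detrend else None
    return GwifaResult(
        query=query,
        cii=cii,
        sobd=sobd,
        fs=fs,
        call=call,
        config=cfg,
        n=counts.size,
        cii_detrended=detrended,
    )
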