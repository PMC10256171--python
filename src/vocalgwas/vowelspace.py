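"""Aggregated vowel measures: quadrilateral vowel space area (VSA4),
formant centralization ratio (FCR), and apparent vocal tract length
from formant spacing (VTL(dF)).

VSA4 is the polygon area spanned by (F2, F1) of the corner vowels
[i, a, o(:=IPA open-o), u]; low values indicate centralized
(dysarthric) speech. FCR = (F2u + F2a + F1i + F1u) / (F2i + F1a) rises
with centralization. VTL treats the vocal tract as a uniform
quarter-wave resonator: F_n = (2n-1)/2 * dF with dF = c / (2 VTL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

SPEED_OF_SOUND_M_S = 353.0  # in warm humid air of the vocal tract
CORNER_VOWELS = ("i", "a", "o", "u")
FCR_VOWELS = ("i", "a", "u")


@dataclass
class VowelSpaceMetrics:
    vsa4: float  # Hz^2
    fcr: float  # dimensionless
    vtl_cm: float
    delta_f_hz: float


def _has(formants: dict, vowel: str, n: int = 2) -> bool:
    f = formants.get(vowel)
    return f is not None and len(f) >= n and all(np.isfinite(f[i]) for i in range(n))


def vsa4(formants: dict[str, tuple]) -> float:
    """Quadrilateral vowel space area in Hz^2 from corner-vowel (F1, F2).

    ``formants`` maps vowel label -> (F1, F2, ...). Vertices are taken
    in (F2, F1) space and ordered by angle around their centroid
    (convex-hull order for a convex quadrilateral), making the area
    invariant to how the vowels are labeled; the shoelace formula gives
    the area. Returns NaN when any corner vowel is missing.
    """
    if not all(_has(formants, v) for v in CORNER_VOWELS):
        return float("nan")
    pts = np.array([(formants[v][1], formants[v][0]) for v in CORNER_VOWELS], dtype=float)
    centroid = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0]))
    p = pts[order]
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def fcr(formants: dict[str, tuple]) -> float:
    """Formant centralization ratio from [i, a, u]."""
    if not all(_has(formants, v) for v in FCR_VOWELS):
        return float("nan")
    f1i, f2i = formants["i"][0], formants["i"][1]
    f1a, f2a = formants["a"][0], formants["a"][1]
    f1u, f2u = formants["u"][0], formants["u"][1]
    denom = f2i + f1a
    if denom == 0:
        raise ZeroDivisionError("FCR denominator F2[i] + F1[a] is zero")
    return float((f2u + f2a + f1i + f1u) / denom)


def delta_f_and_vtl(f1_to_f4, c: float = SPEED_OF_SOUND_M_S) -> tuple[float, float]:
    """Formant spacing dF (Hz) and apparent VTL (cm) from F1..F4.

    dF is the least-squares slope through the origin of F_n against the
    quarter-wave mode numbers (2n-1)/2; VTL = c / (2 dF), in cm.
    Returns (NaN, NaN) if any formant is missing.
    """
    f = np.asarray(f1_to_f4, dtype=float)
    if f.size != 4 or not np.all(np.isfinite(f)):
        return float("nan"), float("nan")
    k = (2.0 * np.arange(1, 5) - 1.0) / 2.0
    delta_f = float(np.dot(f, k) / np.dot(k, k))
    vtl_cm = c / (2.0 * delta_f) * 100.0
    return delta_f, vtl_cm


def vowel_space_metrics(formants: dict[str, tuple],
                        c: float = SPEED_OF_SOUND_M_S) -> VowelSpaceMetrics:
    """All three aggregate measures; VTL averages dF-based estimates
    over every vowel with a complete F1..F4."""
    dfs = [delta_f_and_vtl(formants[v][:4], c)[0] for v in formants
           if _has(formants, v, 4)]
    if dfs:
        mean_df = float(np.mean(dfs))
        vtl = c / (2.0 * mean_df) * 100.0
    else:
        mean_df, vtl = float("nan"), float("nan")
    return VowelSpaceMetrics(vsa4=vsa4(formants), fcr=fcr(formants),
                             vtl_cm=vtl, delta_f_hz=mean_df)


def aggregate_tokens(values) -> float:
    """Arithmetic mean over non-missing token values (raw scale).

    Returns NaN when every token is missing. The catalog stores
    log(mean); the log is taken downstream.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    return float(v.mean()) if v.size else float("nan")
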