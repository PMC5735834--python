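"""Observer-agreement statistics and the gold-standard mass comparison.

Two relative-difference conventions coexist and are never interchanged:
observer studies normalize each pairwise difference to the *average* of the
pair, while the gold-standard comparison normalizes to the *gold* value.
Significance uses a two-tailed paired Student's t-test with no
multiple-testing correction; stars mark p <= 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import logger

PARAMETERS = ("EDV", "ESV", "EF", "LVM")
CONDITION_ORDER = ("raw", "aniso", "tv", "ornlm")


@dataclass(frozen=True)
class AgreementRow:
    """One line of an agreement table: a parameter under one condition."""

    parameter: str
    mean_diff: float
    sd_diff: float
    mean_rel_pct: float
    sd_rel_pct: float
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("correlation out of [-1, 1]")
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value out of [0, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3 subjects")


def _as_vectors(a, b, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D vectors of equal length")
    if a.size < min_len:
        raise ValueError(f"need at least {min_len} pairs, got {a.size}")
    return a, b


def paired_differences(reference, other) -> tuple[float, float, float, float]:
    """Absolute and relative (percent of the pair average) paired differences.

    Returns ``(mean_diff, sd_diff, mean_rel_pct, sd_rel_pct)`` with SDs using
    the n - 1 denominator; differences are ``reference - other``.
    """
    ref, oth = _as_vectors(reference, other, 2)
    d = ref - oth
    avg = (ref + oth) / 2.0
    zero = np.nonzero(avg == 0)[0]
    if zero.size:
        raise ValueError(f"pair {int(zero[0])} averages to zero; relative difference undefined")
    rel = 100.0 * d / avg
    return (
        float(d.mean()),
        float(d.std(ddof=1)),
        float(rel.mean()),
        float(rel.std(ddof=1)),
    )


def pearson_r(a, b) -> float:
    """Sample Pearson correlation (direct covariance formula)."""
    x, y = _as_vectors(a, b, 3)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd * xd).sum()))
    sy = float(np.sqrt((yd * yd).sum()))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant input")
    return float((xd * yd).sum() / (sx * sy))


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-tailed paired Student's t-test: ``t = mean(d) / (sd(d) / sqrt(n))``.

    Identical measurements give ``(0.0, 1.0)``; a zero-SD vector of nonzero
    differences is a degenerate test and raises.
    """
    x, y = _as_vectors(a, b, 3)
    d = x - y
    n = d.size
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        raise ValueError("all differences identical and nonzero; t-test degenerate")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


def exvivo_comparison(lvm_image, lvm_gold) -> tuple[float, float, float]:
    """Percent error of image-derived mass against the gold-standard mass.

    ``pct_i = 100 * (image_i - gold_i) / gold_i`` — the denominator is the gold
    value, not the pair average.  Returns ``(mean_pct, sd_pct, r)``.
    """
    img, gold = _as_vectors(lvm_image, lvm_gold, 3)
    if np.any(gold <= 0):
        raise ValueError("gold-standard masses must be positive")
    pct = 100.0 * (img - gold) / gold
    return float(pct.mean()), float(pct.std(ddof=1)), pearson_r(img, gold)


def significance_stars(p: float) -> str:
    """Footnote stars: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def _safe_pearson(a, b) -> float:
    try:
        return pearson_r(a, b)
    except ValueError:
        logger.warning("correlation undefined (constant input); reported as NaN")
        return float("nan")


def _agreement_row(parameter: str, ref: np.ndarray, oth: np.ndarray) -> AgreementRow:
    mean_diff, sd_diff, mean_rel, sd_rel = paired_differences(ref, oth)
    try:
        _, p = paired_ttest(ref, oth)
    except ValueError:
        logger.warning("degenerate paired t-test for %s; p reported as NaN", parameter)
        p = float("nan")
    return AgreementRow(
        parameter=parameter,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        mean_rel_pct=mean_rel,
        sd_rel_pct=sd_rel,
        r=_safe_pearson(ref, oth),
        p=p,
        n=int(ref.size),
    )


def _row_dict(study: str, condition: str, observer: str, row: AgreementRow) -> dict:
    return {
        "study": study,
        "condition": condition,
        "observer": observer,
        "parameter": row.parameter,
        "mean_diff": row.mean_diff,
        "sd_diff": row.sd_diff,
        "mean_rel_pct": row.mean_rel_pct,
        "sd_rel_pct": row.sd_rel_pct,
        "r": row.r,
        "p": row.p,
        "n": row.n,
        "stars": significance_stars(row.p),
    }


def build_table(measurements: pd.DataFrame, lvm_gold: pd.Series | dict | None = None) -> pd.DataFrame:
    """Intra-/inter-observer and gold-standard agreement tables.

    ``measurements`` is long-format with columns ``condition, subject,
    observer, repeat, parameter, value``; observers are 1 and 2, repeats start
    at 1, and observer 1 repeat 1 is the reference measurement.  Per condition
    and parameter this emits the intra-observer row (observer 1, repeat 1 vs 2)
    and the inter-observer row (observer 1 vs observer 2); with ``lvm_gold``
    (subject -> gold mass, mg) it appends the LVM-only gold-standard rows per
    observer.  Missing repeats drop their row with a logged warning.
    """
    required = {"condition", "subject", "observer", "repeat", "parameter", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    conditions = [c for c in CONDITION_ORDER if c in set(measurements["condition"])]
    conditions += [c for c in measurements["condition"].unique() if c not in conditions]
    rows: list[dict] = []
    for condition in conditions:
        sub = measurements[measurements["condition"] == condition]
        for parameter in PARAMETERS:
            pv = sub[sub["parameter"] == parameter]
            wide = pv.pivot_table(
                index="subject", columns=["observer", "repeat"], values="value"
            ).sort_index()
            if (1, 1) not in wide.columns:
                raise ValueError(f"{condition}/{parameter}: reference (observer 1, repeat 1) missing")
            ref = wide[(1, 1)].to_numpy()
            for study, key, label in (("intra", (1, 2), "1"), ("inter", (2, 1), "2")):
                if key not in wide.columns:
                    logger.warning("%s/%s: missing observer %s repeat %s; row omitted",
                                   condition, parameter, key[0], key[1])
                    continue
                other = wide[key].to_numpy()
                ok = ~(np.isnan(ref) | np.isnan(other))
                rows.append(_row_dict(study, condition, label, _agreement_row(parameter, ref[ok], other[ok])))
        if lvm_gold is not None:
            gold = pd.Series(lvm_gold).sort_index()
            lv = sub[sub["parameter"] == "LVM"]
            wide = lv.pivot_table(index="subject", columns=["observer", "repeat"], values="value").sort_index()
            for obs in (1, 2):
                if (obs, 1) not in wide.columns:
                    logger.warning("%s/LVM gold: observer %d missing; row omitted", condition, obs)
                    continue
                img = wide[(obs, 1)].reindex(gold.index).to_numpy()
                mean_pct, sd_pct, r = exvivo_comparison(img, gold.to_numpy())
                _, p = paired_ttest(img, gold.to_numpy())
                rows.append({
                    "study": "gold",
                    "condition": condition,
                    "observer": str(obs),
                    "parameter": "LVM",
                    "mean_diff": float(np.mean(img - gold.to_numpy())),
                    "sd_diff": float(np.std(img - gold.to_numpy(), ddof=1)),
                    "mean_rel_pct": mean_pct,
                    "sd_rel_pct": sd_pct,
                    "r": r,
                    "p": p,
                    "n": int(gold.size),
                    "stars": significance_stars(p),
                })
    return pd.DataFrame(rows)
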