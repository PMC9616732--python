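"""Encoding-sleep topographic overlap and its group statistics.

Per participant, the encoding topography (per-channel collapsed power
change) is correlated across channels (Spearman's rho) with each sleep
topography (amplitude, duration, density for spindles and SOs); because
encoding engagement shows as a power *decrease* and the sleep measures are
positively scaled, overlap is signified by negative correlations.  Fisher-z
values feed a 2 (event type) x 3 (characteristic) repeated-measures ANOVA
with Holm-corrected post-hoc t-tests, partial rank correlations between
spindle characteristics, the across-participant correlation with the
behavioral retention score, and two topography-shuffling permutation nulls
that test whether the behavior link depends on participant-specific
encoding (or spindle) topographies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .behavior import fisher_z
from .encoding import EncodingTopography
from .events import EventTopography

CHARACTERISTICS = ("amplitude", "duration", "density")


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks.

    NaN entries are removed pairwise; fewer than 3 complete pairs or zero
    rank variance yields NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if x.size < 3:
        return float("nan")
    rx, ry = _midranks(x), _midranks(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class OverlapResult:
    """Encoding-sleep topographic overlap for one participant and measure."""

    participant_id: str
    kind: str
    characteristic: str
    rho: float
    z: float
    n_channels: int


def overlap(enc: EncodingTopography, topo: EventTopography,
            characteristic: str) -> OverlapResult:
    """Across-channel Spearman correlation of encoding vs sleep topography."""
    if characteristic not in CHARACTERISTICS:
        raise ValueError(f"unknown characteristic {characteristic!r}")
    sleep_vec = topo.vector(characteristic)
    common = [ch for ch in enc.channel_labels if ch in sleep_vec.index]
    if len(common) < 10:
        raise ValueError(f"only {len(common)} common channels (< 10)")
    enc_series = pd.Series(enc.values, index=enc.channel_labels)
    rho = spearman(enc_series[common].to_numpy(),
                   sleep_vec[common].to_numpy())
    return OverlapResult(enc.participant_id, topo.kind, characteristic,
                         rho, float(fisher_z(rho)), len(common))


def partial_spearman(x, y, control) -> float:
    """First-order partial rank correlation of x and y given the control.

    All three vectors are mid-rank transformed (after listwise deletion of
    incomplete entries); the partial product-moment correlation
    (r_xy - r_xc r_yc) / sqrt((1 - r_xc^2)(1 - r_yc^2)) is returned.
    Degenerate control correlations (|r| = 1) yield NaN.
    """
    x, y, c = (np.asarray(v, dtype=float) for v in (x, y, control))
    good = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[good], y[good], c[good]
    if x.size < 4:
        return float("nan")
    rx, ry, rc = _midranks(x), _midranks(y), _midranks(c)
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xc = np.corrcoef(rx, rc)[0, 1]
    r_yc = np.corrcoef(ry, rc)[0, 1]
    if max(abs(r_xc), abs(r_yc)) >= 1 - 1e-12:
        return float("nan")
    denom = (1 - r_xc ** 2) * (1 - r_yc ** 2)
    return float((r_xy - r_xc * r_yc) / np.sqrt(denom))


def _as_cell_array(z_table) -> np.ndarray:
    """Coerce a participants x 2 x 3 table of Fisher-z overlaps."""
    if isinstance(z_table, pd.DataFrame):
        cols = [f"{ev}_{ch}" for ev in ("spindle", "so")
                for ch in CHARACTERISTICS]
        missing = [c for c in cols if c not in z_table.columns]
        if missing:
            raise ValueError(f"z table lacks columns {missing}")
        arr = z_table[cols].to_numpy(float).reshape(-1, 2, 3)
    else:
        arr = np.asarray(z_table, dtype=float)
    if arr.ndim != 3 or arr.shape[1:] != (2, 3):
        raise ValueError("expected shape (participants, 2, 3)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("missing cells in the z table")
    return arr


def _f_p(ss_eff: float, df1: int, ss_err: float, df2: int,
         ss_scale: float) -> tuple[float, float, float]:
    # SS below numerical noise (relative to the table's total SS) count
    # as exactly zero, so an all-equal table yields F = 0, p = 1
    eps = 1e-12 * max(ss_scale, 1e-300)
    if ss_eff <= eps and ss_err <= eps:
        return 0.0, 1.0, 0.0
    if ss_err <= eps:
        return float("inf"), 0.0, 1.0
    f = (ss_eff / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta = ss_eff / (ss_eff + ss_err)
    return float(f), p, float(eta)


def rm_anova_2x3(z_table) -> pd.DataFrame:
    """Two-way fully repeated-measures ANOVA on the 2 x 3 overlap table.

    Factors: event type (spindles vs SOs, df 1, n-1) and characteristic
    (amplitude/duration/density, df 2, 2(n-1)), plus their interaction.
    Reports F, uncorrected p (no sphericity correction) and partial eta
    squared SS_effect / (SS_effect + SS_error) per effect.
    """
    y = _as_cell_array(z_table)
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    grand = y.mean()
    m_subj = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_ia = y.mean(axis=2)
    m_ib = y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum(
        (m_ia - m_subj[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum(
        (m_ib - m_subj[:, None] - m_b[None, :] + grand) ** 2)
    ss_subj = a * b * np.sum((m_subj - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_subj - ss_as - ss_bs

    rows = []
    for name, ss_eff, df1, ss_err, df2 in [
        ("event_type", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("characteristic", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_abs,
         (a - 1) * (b - 1) * (n - 1)),
    ]:
        f, p, eta = _f_p(ss_eff, df1, ss_err, df2,
                         max(ss_total, (grand * y.size) ** 2))
        rows.append({"effect": name, "SS": ss_eff, "SS_error": ss_err,
                     "df1": df1, "df2": df2, "F": f, "p": p,
                     "partial_eta_sq": eta})
    return pd.DataFrame(rows)


def _cohen_d(values: np.ndarray) -> float:
    sd = values.std(ddof=1)
    return float(values.mean() / sd) if sd > 0 else 0.0


def _t_1samp(values: np.ndarray) -> tuple[float, float]:
    """One-sample t vs 0; a zero-variance zero-mean sample gives t=0, p=1."""
    if values.std(ddof=1) == 0:
        if values.mean() == 0:
            return 0.0, 1.0
        return float(np.inf) * np.sign(values.mean()), 0.0
    t, p = sps.ttest_1samp(values, 0.0)
    return float(t), float(p)


def posthoc_tests(z_table) -> pd.DataFrame:
    """Post-hoc t-tests on the overlap table, Holm-corrected per family.

    Family 1: paired t-tests spindle vs SO for each characteristic.
    Family 2: one-sample t-tests of each spindle characteristic against 0.
    Cohen's d is mean/SD of the tested difference (or of the values for
    one-sample tests).
    """
    y = _as_cell_array(z_table)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for k, ch in enumerate(CHARACTERISTICS):
        diff = y[:, 0, k] - y[:, 1, k]
        t, p = _t_1samp(diff)
        rows.append({"test": f"spindle_vs_so_{ch}", "family": "paired",
                     "mean": float(diff.mean()), "t": t,
                     "df": n - 1, "p": p, "cohen_d": _cohen_d(diff)})
    for k, ch in enumerate(CHARACTERISTICS):
        vals = y[:, 0, k]
        t, p = _t_1samp(vals)
        rows.append({"test": f"spindle_{ch}_vs_zero", "family": "one_sample",
                     "mean": float(vals.mean()), "t": t,
                     "df": n - 1, "p": p, "cohen_d": _cohen_d(vals)})
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for fam in out["family"].unique():
        sel = out["family"] == fam
        out.loc[sel, "p_holm"] = multipletests(out.loc[sel, "p"],
                                               method="holm")[1]
    return out


def holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="holm")[1]


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n)."""
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    xs = (rx - rx.mean()) / rx.std()
    ys = (ry - ry.mean()) / ry.std()
    null = (ys[perms] * xs).mean(axis=1)
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


def behavior_correlation(overlap_z, retention_pct,
                         exact_n_max: int = 9) -> tuple[float, float]:
    """Spearman correlation of per-participant overlap z with retention %.

    Returns (rho, p).  The p-value is exact (full permutation enumeration)
    for n <= ``exact_n_max`` and the usual t-approximation otherwise.
    """
    x = np.asarray(overlap_z, dtype=float)
    y = np.asarray(retention_pct, dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if x.size < 5:
        raise ValueError("need at least 5 participants")
    rho = spearman(x, y)
    if not np.isfinite(rho):
        return float("nan"), float("nan")
    n = x.size
    if n <= exact_n_max:
        p = _exact_spearman_p(_midranks(x), _midranks(y), rho)
    else:
        t = rho * np.sqrt((n - 2) / max(1 - rho ** 2, 1e-12))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return rho, p


@dataclass
class PermutationNull:
    """Topography-shuffling null for the overlap-behavior correlation."""

    shuffled: str
    observed_r: float
    null: np.ndarray
    p: float
    p_two_sided: float
    n_perm: int


def _overlap_matrix(enc: np.ndarray, spin: np.ndarray) -> np.ndarray:
    """All-pairs Spearman matrix C[i, j] = rho(enc_i, spin_j)."""
    n = enc.shape[0]
    if np.all(np.isfinite(enc)) and np.all(np.isfinite(spin)):
        er = np.apply_along_axis(_midranks, 1, enc)
        sr = np.apply_along_axis(_midranks, 1, spin)
        er = (er - er.mean(1, keepdims=True)) / er.std(1, keepdims=True)
        sr = (sr - sr.mean(1, keepdims=True)) / sr.std(1, keepdims=True)
        return er @ sr.T / enc.shape[1]
    c = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            c[i, j] = spearman(enc[i], spin[j])
    return c


def permutation_null(enc_topos, spindle_topos, retention_pct,
                     shuffle_which: str, n_perm: int = 1000,
                     rng: np.random.Generator | int | None = None
                     ) -> PermutationNull:
    """Null distribution for the overlap-behavior correlation.

    Each permutation shuffles one topography set (``"encoding"`` or
    ``"spindle"``) across participants with a uniform random permutation
    (identity allowed), recomputes every participant's overlap rho -> z,
    correlates (Spearman) with the unshuffled retention scores, and records
    r.  The reported p is one-sided in the hypothesized direction — overlap
    is signified by *negative* correlations, so small p means the observed
    r lies in the negative tail of the null — with the (1 + #) /
    (1 + n_perm) correction.  A two-sided p on |r| is also kept.  (A
    one-sided p in the *observed* direction would reject at twice the
    nominal rate under the null.)
    """
    if shuffle_which not in ("encoding", "spindle"):
        raise ValueError("shuffle_which must be 'encoding' or 'spindle'")
    enc = np.asarray(enc_topos, dtype=float)
    spin = np.asarray(spindle_topos, dtype=float)
    y = np.asarray(retention_pct, dtype=float)
    if not (enc.shape == spin.shape and enc.shape[0] == y.size):
        raise ValueError("participant counts do not match across inputs")
    if np.nanstd(y) == 0:
        raise ValueError("retention scores are constant: the behavior "
                         "correlation is undefined")
    rng = np.random.default_rng(rng)
    n = enc.shape[0]
    c = _overlap_matrix(enc, spin)
    z_obs = fisher_z(np.diag(c))
    r_obs = spearman(z_obs, y)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        z = fisher_z(c[perm, np.arange(n)] if shuffle_which == "encoding"
                     else c[np.arange(n), perm])
        null[b] = spearman(z, y)
    p = (1 + np.sum(null <= r_obs)) / (1 + n_perm)
    p2 = (1 + np.sum(np.abs(null) >= abs(r_obs))) / (1 + n_perm)
    return PermutationNull(shuffle_which, float(r_obs), null, float(p),
                           float(p2), n_perm)


def coupling_contrast(z_higher, z_lower) -> dict:
    """Paired t-test of overlap z for higher- vs lower-coupling spindles."""
    hi = np.asarray(z_higher, dtype=float)
    lo = np.asarray(z_lower, dtype=float)
    good = np.isfinite(hi) & np.isfinite(lo)
    hi, lo = hi[good], lo[good]
    if hi.size < 2:
        raise ValueError("need at least 2 participants")
    t, p = _t_1samp(hi - lo)
    return {"t": t, "df": hi.size - 1, "p": p,
            "mean_diff": float((hi - lo).mean()),
            "cohen_d": _cohen_d(hi - lo), "n": int(hi.size)}
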