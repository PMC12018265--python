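"""Split-half temporal consistency and condition comparisons.

Temporal consistency of a channel's band dynamics in one condition is the
mean, over random equal splits of the trials, of the Pearson correlation
between the two half-mean time courses (1000 splits by default; with odd
trial counts the larger half receives the extra trial at random).

Conditions are compared with a multilevel block permutation test: the
statistic is the difference of the channel-mean consistencies, and the null
reassigns condition labels among each participant's observations only
(exchangeability blocks restricted to participants).  Effect sizes are the
raw mean difference and paired Cohen's d; confidence intervals come from a
cluster bootstrap that resamples participants.  The spatial correlation of
consistency across conditions is tested by permuting channel pairings
within participant blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import PermutationResult, cluster_bootstrap_ci, cohens_d_paired

__all__ = ["ConsistencyResult", "split_half_consistency",
           "consistency_table", "condition_difference_test",
           "cross_condition_spatial_correlation"]

DEFAULT_N_SPLITS = 1000


@dataclass
class ConsistencyResult:
    value: float          # mean split-half correlation
    n_splits: int
    n_skipped: int = 0


def split_half_consistency(trials: np.ndarray, n_splits: int = DEFAULT_N_SPLITS,
                           seed: int = 0,
                           rng: np.random.Generator | None = None) -> ConsistencyResult:
    """Mean split-half correlation of a (n_trials, T) array.

    Splits with a constant half-mean series are skipped (they have no
    defined correlation) but still counted in ``n_splits``.
    """
    x = np.asarray(trials, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise ValueError("need a (n_trials >= 4, T) array")
    n = x.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    half = n // 2
    rs = []
    skipped = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        a = x[perm[:half]].mean(axis=0)
        b = x[perm[half:]].mean(axis=0)   # larger half takes the odd trial
        if np.std(a) == 0 or np.std(b) == 0:
            skipped += 1
            continue
        rs.append(np.corrcoef(a, b)[0, 1])
    if skipped:
        warnings.warn(f"{skipped} split(s) had a constant half-mean series; skipped")
    value = float(np.mean(rs)) if rs else np.nan
    return ConsistencyResult(value=value, n_splits=n_splits, n_skipped=skipped)


def consistency_table(condition_data: dict, participants: np.ndarray,
                      n_splits: int = DEFAULT_N_SPLITS, seed: int = 0) -> pd.DataFrame:
    """Tidy table of per-channel, per-condition consistency.

    ``condition_data``: condition -> (n_trials, C, T) warped band amplitudes.
    """
    import zlib
    rows = []
    for cond in sorted(condition_data):
        data = np.asarray(condition_data[cond])
        cond_key = zlib.crc32(cond.encode()) % (2 ** 31)   # process-independent
        for c in range(data.shape[1]):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, cond_key, c]))
            res = split_half_consistency(data[:, c, :], n_splits=n_splits, rng=rng)
            rows.append(dict(participant=int(participants[c]), channel=c,
                             condition=cond, consistency=res.value,
                             n_trials=data.shape[0], n_splits=res.n_splits))
    return pd.DataFrame(rows)


def condition_difference_test(table: pd.DataFrame, cond_a: str, cond_b: str,
                              n_perm: int = 1000, seed: int = 0,
                              alternative: str = "greater") -> PermutationResult:
    """Multilevel block permutation test of consistency(cond_a) - consistency(cond_b).

    Condition labels are permuted only within each participant's block of
    observations.  One-sided by default (``cond_a > cond_b``), matching
    directional hypotheses such as imagination > control.
    """
    a = table[table.condition == cond_a].sort_values("channel")
    b = table[table.condition == cond_b].sort_values("channel")
    if not np.array_equal(a.channel.values, b.channel.values):
        raise ValueError("both conditions must cover the same channels")
    va, vb = a.consistency.values, b.consistency.values
    parts = a.participant.values
    uparts = np.unique(parts)
    if len(uparts) == 1:
        warnings.warn("single participant: permutation is within one block only")
    rng = np.random.default_rng(seed)
    observed = float(va.mean() - vb.mean())
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa = np.empty_like(va)
        pb = np.empty_like(vb)
        for p in uparts:
            sel = parts == p
            pool = np.concatenate([va[sel], vb[sel]])
            perm = rng.permutation(len(pool))
            k = sel.sum()
            pa[sel] = pool[perm[:k]]
            pb[sel] = pool[perm[k:]]
        null[i] = pa.mean() - pb.mean()
    if alternative == "greater":
        k = np.sum(null >= observed)
    elif alternative == "less":
        k = np.sum(null <= observed)
    else:
        k = np.sum(np.abs(null) >= abs(observed))
    p = float((1 + k) / (n_perm + 1))
    diff = va - vb
    ci = cluster_bootstrap_ci(diff, parts, rng)
    return PermutationResult(observed=observed, null=null, p=p, ci=ci,
                             cohens_d=cohens_d_paired(diff),
                             mean_difference=float(diff.mean()),
                             note=f"{cond_a} - {cond_b}, blocks = participants")


def cross_condition_spatial_correlation(table: pd.DataFrame, cond_a: str,
                                        cond_b: str, n_perm: int = 1000,
                                        seed: int = 0) -> PermutationResult:
    """Correlation across channels of consistency in two conditions.

    Inference permutes the channel pairing within participant blocks;
    blocks with fewer than 3 channels are merged into a common pool.
    """
    a = table[table.condition == cond_a].sort_values("channel")
    b = table[table.condition == cond_b].sort_values("channel")
    va, vb = a.consistency.values, b.consistency.values
    if len(va) < 6:
        raise ValueError("need >= 6 channels for a spatial correlation")
    parts = a.participant.values.copy()
    for p in np.unique(parts):
        if np.sum(parts == p) < 3:
            warnings.warn(f"participant block {p} has < 3 channels; merged")
            parts[parts == p] = -1
    rng = np.random.default_rng(seed)
    observed = float(np.corrcoef(va, vb)[0, 1])
    null = np.empty(n_perm)
    for i in range(n_perm):
        vp = vb.copy()
        for p in np.unique(parts):
            sel = np.where(parts == p)[0]
            vp[sel] = vp[rng.permutation(sel)]
        null[i] = np.corrcoef(va, vp)[0, 1]
    p = float((1 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1))
    return PermutationResult(observed=observed, null=null, p=p,
                             note=f"spatial r, {cond_a} vs {cond_b}")
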