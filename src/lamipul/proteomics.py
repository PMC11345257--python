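"""Label-free-quantification differential expression, Perseus-style.

The analysis chain mirrors the standard Perseus workflow for MaxQuant LFQ
matrices: proteins are *detected* when quantified in at least ``min_reps``
replicates of a condition (default 1 of 3); intensities are log2-transformed
and missing observations imputed with the constant 0 *on the log2 scale*;
the two-sample comparison uses the SAM/Perseus s0-moderated t-statistic

    t_s0 = (mean(a) - mean(b)) / (sp * sqrt(1/na + 1/nb) + s0)

with pooled standard deviation sp, and significance is assigned by a
permutation-based volcano cut controlling the FDR (median number of false
positives across group-label permutations divided by the number of observed
positives, scanned over symmetric |t_s0| cuts).

The model object :class:`TwoSampleS0Test` is built from a prepared matrix
and fitted with :meth:`TwoSampleS0Test.fit`, which returns
:class:`TwoSampleS0Results` carrying per-protein estimates, the permutation
cut, and a ``summary()`` table. The spec-level operations
(:func:`s0_t_test`, :func:`permutation_volcano`, ...) are thin wrappers.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, FormatError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LFQ matrix container
# ---------------------------------------------------------------------------

class LfqMatrix:
    """Protein x sample LFQ intensities with (condition, replicate) structure.

    ``intensities`` is a DataFrame indexed by protein id with a two-level
    column MultiIndex (condition, replicate). Missing observations are NaN;
    present values must be >= 0.
    """

    def __init__(self, intensities: pd.DataFrame) -> None:
        if not isinstance(intensities.columns, pd.MultiIndex):
            raise ValidationError("intensities need (condition, replicate) columns")
        conditions = intensities.columns.get_level_values(0).unique()
        if len(conditions) < 2:
            raise ValidationError("an LFQ matrix needs >= 2 conditions")
        rep_counts = {
            c: intensities[c].shape[1] for c in conditions
        }
        if len(set(rep_counts.values())) != 1:
            raise ValidationError(f"unequal replicate counts per condition: {rep_counts}")
        values = intensities.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValidationError("LFQ intensities must be >= 0")
        self.intensities = intensities

    @property
    def proteins(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.intensities.columns.get_level_values(0).unique())

    @property
    def n_replicates(self) -> int:
        return self.intensities[self.conditions[0]].shape[1]

    def condition_values(self, condition: str) -> pd.DataFrame:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return self.intensities[condition]

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   design: Mapping[str, tuple[str, int]] | None = None) -> "LfqMatrix":
        """Build from a flat matrix whose columns are '<condition>_<rep>'.

        ``design`` can override the column -> (condition, replicate) mapping.
        """
        pairs = []
        for col in df.columns:
            if design is not None:
                cond, rep = design[col]
            else:
                cond, _, rep = str(col).rpartition("_")
                if not cond or not rep.isdigit():
                    raise FormatError(f"cannot parse sample column {col!r} as condition_rep")
                rep = int(rep)
            pairs.append((cond, rep))
        out = df.copy()
        out.columns = pd.MultiIndex.from_tuples(pairs, names=["condition", "replicate"])
        return cls(out.sort_index(axis=1))

    @classmethod
    def from_tsv(cls, path: str | Path, index_col: str | int = 0) -> "LfqMatrix":
        df = pd.read_csv(path, sep="\t", index_col=index_col)
        return cls.from_frame(df)

    @classmethod
    def from_proteingroups(cls, path: str | Path,
                           id_column: str = "Protein IDs") -> "LfqMatrix":
        """Read a MaxQuant proteinGroups-like TSV ('LFQ intensity <cond>_<rep>').

        Zero intensities (MaxQuant's missing-value encoding) become NaN;
        rows flagged in 'Reverse' or 'Potential contaminant' are dropped.
        """
        df = pd.read_csv(path, sep="\t")
        if id_column not in df.columns:
            raise FormatError(f"{path}: missing id column {id_column!r}")
        for flag_col in ("Reverse", "Potential contaminant"):
            if flag_col in df.columns:
                df = df[df[flag_col].fillna("") != "+"]
        prefix = "LFQ intensity "
        lfq_cols = [c for c in df.columns if c.startswith(prefix)]
        if not lfq_cols:
            raise FormatError(f"{path}: no '{prefix}<condition>_<rep>' columns")
        matrix = df.set_index(id_column)[lfq_cols].astype(float)
        matrix.columns = [c[len(prefix):] for c in lfq_cols]
        matrix = matrix.replace(0.0, np.nan)
        return cls.from_frame(matrix)

    def to_tsv(self, path: str | Path) -> None:
        flat = self.intensities.copy()
        flat.columns = [f"{c}_{r}" for c, r in flat.columns]
        flat.to_csv(path, sep="\t", index_label="protein_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# detection, overlap, preparation
# ---------------------------------------------------------------------------

def detect_expressed(matrix: LfqMatrix, condition: str, min_reps: int = 1) -> set[str]:
    """Proteins quantified (> 0, non-missing) in >= min_reps replicates."""
    values = matrix.condition_values(condition)
    if min_reps > values.shape[1]:
        raise ConfigError(
            f"min_reps {min_reps} exceeds replicate count {values.shape[1]}"
        )
    counts = ((values > 0) & values.notna()).sum(axis=1)
    return set(values.index[counts >= min_reps])


def condition_overlap(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of a k-way Venn partition.

    Returns counts for all 2^k - 1 non-empty membership regions, keyed by
    the sorted tuple of condition names defining the region. The counts
    always sum to the union cardinality (asserted).
    """
    names = sorted(sets)
    union = set().union(*sets.values()) if sets else set()
    regions = {
        tuple(combo): 0
        for k in range(1, len(names) + 1)
        for combo in itertools.combinations(names, k)
    }
    for item in union:
        member = tuple(n for n in names if item in sets[n])
        regions[member] += 1
    assert sum(regions.values()) == len(union)
    return regions


def prepare(matrix: LfqMatrix) -> pd.DataFrame:
    """log2-transform present intensities; impute missing with constant 0.

    The constant is applied on the log2 scale (Perseus "NaN -> constant 0").
    Raw intensities equal to 0 are treated as missing; raw intensities equal
    to 1 collide with the imputation constant and are logged.
    """
    values = matrix.intensities.to_numpy(dtype=float).copy()
    zero_present = np.count_nonzero(values == 0.0)
    if zero_present:
        logger.info("%d zero intensities treated as missing", zero_present)
        values[values == 0.0] = np.nan
    collisions = np.count_nonzero(values == 1.0)
    if collisions:
        logger.info(
            "%d intensities of exactly 1 log2-transform to 0 and collide "
            "with the imputation constant", collisions
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log2(values)
    logged[np.isnan(logged)] = 0.0
    return pd.DataFrame(logged, index=matrix.intensities.index,
                        columns=matrix.intensities.columns)


# ---------------------------------------------------------------------------
# s0-moderated t-statistic
# ---------------------------------------------------------------------------

def _s0_stats(a: np.ndarray, b: np.ndarray, s0: float):
    """Vectorized s0 t-statistic along the last axis. Returns (diff, t, df)."""
    na, nb = a.shape[-1], b.shape[-1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    if s0 < 0:
        raise ConfigError("s0 must be >= 0")
    diff = a.mean(axis=-1) - b.mean(axis=-1)
    ssa = ((a - a.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    ssb = ((b - b.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    df = na + nb - 2
    sp = np.sqrt((ssa + ssb) / df)
    denom = sp * np.sqrt(1.0 / na + 1.0 / nb) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return diff, t, df


def s0_t_test(a: Sequence[float], b: Sequence[float],
              s0: float = 0.15) -> tuple[float, float, float]:
    """s0-moderated two-sample t-test on two replicate vectors.

    Returns (difference = mean(a) - mean(b), t_s0, two-sided p from Student
    t with na+nb-2 df). With s0 = 0 this is exactly the classical pooled
    two-sample t-test. Zero pooled variance with s0 = 0 gives an infinite
    statistic, reported with p -> 0 and a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff, t, df = _s0_stats(a, b, s0)
    diff, t = float(diff), float(t)
    if np.isinf(t):
        warnings.warn("zero within-group variance with s0=0: infinite t, p -> 0")
        return diff, t, 0.0
    p = 2.0 * stats.t.sf(abs(t), df)
    return diff, t, float(p)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeResult:
    protein_id: str
    difference: float
    t_s0: float
    p_raw: float
    significant: bool
    direction: str  # up | down | ns


class TwoSampleS0Results:
    """Fit results of :class:`TwoSampleS0Test`.

    Attributes
    ----------
    frame : pandas.DataFrame
        Per-protein columns difference, t_s0, p_raw, significant, direction.
    t_cut : float or None
        The symmetric |t_s0| volcano cut; None when nothing is significant.
    estimated_fdr : float or None
        The permutation-FDR estimate realized at the chosen cut.
    """

    def __init__(self, model: "TwoSampleS0Test", frame: pd.DataFrame,
                 t_cut: float | None, estimated_fdr: float | None,
                 n_perm_used: int) -> None:
        self.model = model
        self.frame = frame
        self.t_cut = t_cut
        self.estimated_fdr = estimated_fdr
        self.n_perm_used = n_perm_used

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    def to_records(self) -> list[DeResult]:
        return [
            DeResult(pid, row.difference, row.t_s0, row.p_raw,
                     bool(row.significant), row.direction)
            for pid, row in self.frame.iterrows()
        ]

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["significant"] = out["significant"].astype(int)
        out.to_csv(path, sep="\t", index_label="protein_id", float_format="%.6g")

    def summary(self) -> str:
        m = self.model
        counts = self.frame["direction"].value_counts()
        lines = [
            "Two-sample s0-moderated permutation test",
            "=" * 46,
            f"conditions:        {m.cond_a} vs {m.cond_b}",
            f"proteins:          {len(self.frame)}",
            f"replicates:        {m.na} vs {m.nb}",
            f"s0:                {m.s0}",
            f"FDR level:         {m.fdr}",
            f"permutations used: {self.n_perm_used}",
            f"|t| volcano cut:   "
            + ("none (no protein significant)" if self.t_cut is None
               else f"{self.t_cut:.4f} (est. FDR {self.estimated_fdr:.4f})"),
            f"significant:       {self.n_significant} "
            f"(up {counts.get('up', 0)}, down {counts.get('down', 0)})",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Volcano plot: difference vs -log10 raw p, significant points marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.frame
        neglog = -np.log10(np.clip(f["p_raw"], 1e-300, None))
        sig = f["significant"].to_numpy(dtype=bool)
        ax.scatter(f["difference"][~sig], neglog[~sig], s=6, c="0.6", label="ns")
        ax.scatter(f["difference"][sig], neglog[sig], s=8, c="crimson",
                   label="significant")
        ax.set_xlabel(f"difference (log2 {self.model.cond_a} - {self.model.cond_b})")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax


class TwoSampleS0Test:
    """s0-moderated two-sample test with permutation-FDR volcano significance.

    Parameters
    ----------
    prepared : pandas.DataFrame
        log2-imputed matrix from :func:`prepare` (MultiIndex columns).
    cond_a, cond_b : str
        Conditions to compare; difference is mean(a) - mean(b).
    s0 : float
        Background-variance offset added to the t denominator.
    fdr : float
        Target permutation FDR for the volcano cut.
    """

    def __init__(self, prepared: pd.DataFrame, cond_a: str, cond_b: str,
                 s0: float = 0.15, fdr: float = 0.05) -> None:
        conditions = prepared.columns.get_level_values(0)
        for cond in (cond_a, cond_b):
            if cond not in set(conditions):
                raise KeyError(f"condition {cond!r} not in matrix")
        self.prepared = prepared
        self.cond_a, self.cond_b = cond_a, cond_b
        self.s0, self.fdr = s0, fdr
        self._a = prepared[cond_a].to_numpy(dtype=float)
        self._b = prepared[cond_b].to_numpy(dtype=float)
        self.na, self.nb = self._a.shape[1], self._b.shape[1]

    def fit(self, n_perm: int = 250, seed: int | None = 0) -> TwoSampleS0Results:
        """Run the test and the permutation volcano cut.

        Group-label permutations reassign the pooled na+nb samples to the
        two groups; when fewer distinct assignments exist than ``n_perm``
        the exhaustive set is used (with a warning). Deterministic for a
        fixed seed.
        """
        if n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        diff, t_obs, df = _s0_stats(self._a, self._b, self.s0)
        abs_t = np.abs(t_obs)
        n_inf = np.count_nonzero(np.isinf(t_obs))
        if n_inf:
            warnings.warn(f"{n_inf} proteins with zero variance and s0=0: p -> 0")
        p_raw = np.where(np.isinf(t_obs), 0.0, 2.0 * stats.t.sf(
            np.where(np.isinf(abs_t), 0.0, abs_t), df))

        pooled = np.concatenate([self._a, self._b], axis=1)
        n_total = self.na + self.nb
        all_assign = list(itertools.combinations(range(n_total), self.na))
        if len(all_assign) <= n_perm:
            if len(all_assign) < n_perm:
                warnings.warn(
                    f"only {len(all_assign)} distinct group-label permutations; "
                    f"using the exhaustive set instead of {n_perm}"
                )
            assignments = all_assign
        else:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(all_assign), size=n_perm, replace=False)
            assignments = [all_assign[i] for i in sorted(idx)]

        perm_abs_t = np.empty((len(assignments), pooled.shape[0]))
        for k, group_a in enumerate(assignments):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(group_a)] = True
            _, t_perm, _ = _s0_stats(pooled[:, mask], pooled[:, ~mask], self.s0)
            perm_abs_t[k] = np.abs(t_perm)

        t_cut, est_fdr = self._volcano_cut(abs_t, perm_abs_t)
        significant = np.zeros(len(abs_t), dtype=bool) if t_cut is None \
            else abs_t >= t_cut
        direction = np.where(
            ~significant, "ns",
            np.where(diff > 0, "up", np.where(diff < 0, "down", "ns")),
        )

        frame = pd.DataFrame({
            "difference": diff,
            "t_s0": t_obs,
            "p_raw": p_raw,
            "significant": significant,
            "direction": direction,
        }, index=self.prepared.index)
        return TwoSampleS0Results(self, frame, t_cut, est_fdr, len(assignments))

    def _volcano_cut(self, abs_t: np.ndarray,
                     perm_abs_t: np.ndarray) -> tuple[float | None, float | None]:
        """Smallest symmetric |t| cut whose estimated FDR is <= the target.

        Estimated FDR at cut c = median over permutations of #{|t_perm| >= c}
        divided by #{|t_obs| >= c}. A non-positive target admits no cut
        (zero false discoveries cannot be certified by permutation).
        """
        if self.fdr <= 0:
            return None, None
        finite = abs_t[np.isfinite(abs_t)]
        if finite.size == 0:
            return None, None
        cuts = np.unique(finite)  # ascending candidate cuts
        n_pos = finite.size - np.searchsorted(np.sort(finite), cuts, side="left")
        n_pos = n_pos + np.count_nonzero(np.isinf(abs_t))
        sorted_perm = np.sort(perm_abs_t, axis=1)
        fp = np.empty((perm_abs_t.shape[0], cuts.size))
        for k in range(perm_abs_t.shape[0]):
            fp[k] = perm_abs_t.shape[1] - np.searchsorted(sorted_perm[k], cuts,
                                                          side="left")
        median_fp = np.median(fp, axis=0)
        est = median_fp / np.maximum(n_pos, 1)
        ok = np.nonzero(est <= self.fdr)[0]
        if ok.size == 0:
            return None, None
        best = ok[0]  # smallest qualifying cut -> most inclusive
        return float(cuts[best]), float(est[best])


# ---------------------------------------------------------------------------
# spec-level convenience operations
# ---------------------------------------------------------------------------

def permutation_volcano(
    prepared: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    s0: float = 0.15,
    fdr: float = 0.05,
    n_perm: int = 250,
    seed: int | None = 0,
) -> list[DeResult]:
    """One-shot wrapper: fit :class:`TwoSampleS0Test` and return records."""
    model = TwoSampleS0Test(prepared, cond_a, cond_b, s0=s0, fdr=fdr)
    return model.fit(n_perm=n_perm, seed=seed).to_records()


def call_direction(results: Iterable[DeResult]) -> list[DeResult]:
    """(Re)assign direction: up/down only for significant proteins."""
    out = []
    for r in results:
        if not r.significant or r.difference == 0:
            direction = "ns"
        else:
            direction = "up" if r.difference > 0 else "down"
        out.append(DeResult(r.protein_id, r.difference, r.t_s0, r.p_raw,
                            r.significant, direction))
    return out


def differential_expression(
    matrix: LfqMatrix,
    cond_a: str,
    cond_b: str,
    s0: float = 0.15,
    fdr: float = 0.05,
    n_perm: int = 250,
    seed: int | None = 0,
) -> TwoSampleS0Results:
    """Full chain: prepare (log2 + constant-0 imputation) then fit the test."""
    model = TwoSampleS0Test(prepare(matrix), cond_a, cond_b, s0=s0, fdr=fdr)
    return model.fit(n_perm=n_perm, seed=seed)
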