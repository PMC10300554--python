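"""Differential chromatin-state analysis across small case/control cohorts.

Per-sample genome segmentations (one state per 200-bp bin, 14 states by
default) are compared between groups bin by bin.  For each polymorphic bin
and each state, group association is scored with a two-sided Fisher exact
test on the state's presence/absence pattern; because the cohorts are tiny
(4 vs 4 by default), significance is calibrated with an exhaustive label
permutation over all C(8, 4) = 70 case/control assignments, so the most
significant empirical p-value attainable is 1/70.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StateMatrix:
    """Chromatin-state calls for a cohort: one state per bin per sample.

    ``bins`` is a DataFrame with ``chrom``, ``start``, ``end`` (fixed-width
    bins); ``states`` is an (n_bins, n_samples) integer array with 1-based
    state labels; ``groups`` assigns each sample to ``"case"`` or
    ``"control"``.
    """

    bins: pd.DataFrame
    states: np.ndarray
    samples: list
    groups: list
    n_states: int = 14
    quiescent_state: int = 14

    def __post_init__(self):
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-d (bins x samples) array")
        if self.states.shape != (len(self.bins), len(self.samples)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.bins)} bins x {len(self.samples)} samples"
            )
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label required per sample")
        bad = set(self.groups) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.states.min() < 1 or self.states.max() > self.n_states:
            raise ValueError(
                f"state labels must lie in 1..{self.n_states}, "
                f"found range [{self.states.min()}, {self.states.max()}]"
            )
        widths = (self.bins["end"] - self.bins["start"]).unique()
        if len(widths) != 1:
            raise ValueError("all bins must share one fixed width")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def case_idx(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == "case"])

    @property
    def control_idx(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == "control"])

    def presence(self, state: int) -> np.ndarray:
        """Boolean (bins x samples) matrix: state called in that sample."""
        return self.states == state


def write_segmentation_bed(sm: StateMatrix, sample: str, path) -> None:
    """Write one sample's segmentation as BED with run-merged state blocks."""
    j = sm.samples.index(sample)
    col = sm.states[:, j]
    chroms = sm.bins["chrom"].to_numpy()
    starts = sm.bins["start"].to_numpy()
    ends = sm.bins["end"].to_numpy()
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, sm.n_bins + 1):
            if (
                i == sm.n_bins
                or col[i] != col[run_start]
                or chroms[i] != chroms[run_start]
                or starts[i] != ends[i - 1]
            ):
                fh.write(
                    f"{chroms[run_start]}\t{starts[run_start]}\t{ends[i - 1]}\t"
                    f"E{col[run_start]}\n"
                )
                run_start = i


def read_segmentation_beds(
    paths: dict, groups: dict, bin_size: int = 200, n_states: int = 14,
    quiescent_state: int = 14,
) -> StateMatrix:
    """Assemble a StateMatrix from per-sample BED segmentations.

    ``paths`` maps sample name to BED path; ``groups`` maps sample name to
    "case"/"control".  All samples must tile the same bins.
    """
    samples = list(paths)
    per_sample = {}
    for s in samples:
        rows = []
        with open(paths[s]) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, label = line.split()[:4]
                state = int(label.lstrip("E"))
                for b in range(int(start), int(end), bin_size):
                    rows.append((chrom, b, state))
        per_sample[s] = rows
    ref = per_sample[samples[0]]
    keys = [(c, b) for c, b, _ in ref]
    for s in samples[1:]:
        if [(c, b) for c, b, _ in per_sample[s]] != keys:
            raise ValueError(f"sample {s} does not tile the same bins")
    states = np.column_stack(
        [[st for _, _, st in per_sample[s]] for s in samples]
    )
    bins = pd.DataFrame(
        {"chrom": [c for c, _ in keys],
         "start": [b for _, b in keys],
         "end": [b + bin_size for _, b in keys]}
    )
    return StateMatrix(bins, states, samples, [groups[s] for s in samples],
                       n_states, quiescent_state)


# ---------------------------------------------------------------------------
# Polymorphic-bin selection
# ---------------------------------------------------------------------------


def select_polymorphic_bins(sm: StateMatrix, state: int | None = None) -> np.ndarray:
    """Indices of bins worth testing.

    Global mode (``state is None``): keep bins where at least two distinct
    states occur across samples and the quiescent state is called in
    strictly fewer than two thirds of samples.  Per-state mode: keep bins
    where ``state`` is called in at least one third of samples.
    """
    if state is None:
        n_distinct = np.array([len(np.unique(row)) for row in sm.states])
        quies = (sm.states == sm.quiescent_state).sum(axis=1)
        keep = (n_distinct >= 2) & (quies < 2 * sm.n_samples / 3)
    else:
        if not 1 <= state <= sm.n_states:
            raise ValueError(f"state {state} outside 1..{sm.n_states}")
        keep = (sm.states == state).sum(axis=1) >= sm.n_samples / 3
    return np.where(keep)[0]


# ---------------------------------------------------------------------------
# Per-bin tests
# ---------------------------------------------------------------------------


def fisher_presence_test(a: int, b: int, n_cases: int, n_controls: int) -> float:
    """Two-sided Fisher exact p for a state's presence pattern: ``a`` of
    ``n_cases`` cases and ``b`` of ``n_controls`` controls carry the state.

    The two-sided rule sums hypergeometric probabilities of all tables with
    the same margins that are no more probable than the observed one; the
    fully separated 4-vs-4 pattern (a=4, b=0) gives p = 2/70.
    """
    if not (0 <= a <= n_cases and 0 <= b <= n_controls):
        raise ValueError("presence counts exceed group sizes")
    _, p = stats.fisher_exact(
        [[a, n_cases - a], [b, n_controls - b]], alternative="two-sided"
    )
    return float(p)


def bin_presence_test(sm: StateMatrix, bin_index: int, state: int) -> dict:
    """Fisher presence test for one state at one bin of a StateMatrix."""
    pres = sm.states[bin_index] == state
    a = int(pres[sm.case_idx].sum())
    b = int(pres[sm.control_idx].sum())
    nc, nh = len(sm.case_idx), len(sm.control_idx)
    return {"bin": bin_index, "state": state, "case_present": a,
            "control_present": b, "p": fisher_presence_test(a, b, nc, nh)}


def _pvalue_table(n_cases: int, n_controls: int) -> np.ndarray:
    """Fisher two-sided p for every (cases-present, controls-present) pair."""
    tab = np.empty((n_cases + 1, n_controls + 1))
    for a in range(n_cases + 1):
        for b in range(n_controls + 1):
            _, tab[a, b] = stats.fisher_exact(
                [[a, n_cases - a], [b, n_controls - b]], alternative="two-sided"
            )
    return tab


@dataclass
class PermutationResult:
    """Per-state outcome of the exhaustive label-permutation test."""

    state: int
    k_obs: int
    counts: np.ndarray  # significant-bin count under every labeling
    empirical_p: float
    n_labelings: int
    bins: pd.DataFrame  # per-bin presence counts and Fisher p (observed labels)

    @property
    def significant_bins(self) -> pd.DataFrame:
        return self.bins[self.bins["significant"]]


def permutation_state_test(
    sm: StateMatrix,
    state: int,
    alpha: float = 0.05,
    bins: np.ndarray | None = None,
) -> PermutationResult:
    """Exhaustive label-permutation test for one state.

    Over the state's polymorphic bins, the statistic is the number of bins
    whose presence pattern gives a two-sided Fisher p < ``alpha``.  That
    count is recomputed under every possible assignment of the case label
    to ``n_cases`` of the samples — all C(n_samples, n_cases) of them, the
    observed assignment included — and the empirical p-value is

        p_emp = (1 + #{labelings with count strictly greater than
                        observed}) / n_labelings

    With 4 + 4 samples there are C(8, 4) = 70 labelings, so the smallest
    attainable p is 1/70.  The strict-greater convention is deliberate: the
    complement of the observed labeling always ties the observed count
    under a two-sided per-bin test, so counting ties could never reach that
    floor.  A state with no significant bin under the observed labels
    (k_obs = 0) is non-assessable and reported with p = 1.
    """
    if not 1 <= state <= sm.n_states:
        raise ValueError(f"state {state} outside 1..{sm.n_states}")
    if bins is None:
        bins = select_polymorphic_bins(sm, state=state)
    nc, nh = len(sm.case_idx), len(sm.control_idx)
    n = sm.n_samples
    labelings = list(itertools.combinations(range(n), nc))
    L = len(labelings)
    if L < 20:
        warnings.warn(
            f"only {L} label permutations available; empirical p floor is "
            f"{1 / L:.3g}", stacklevel=2
        )
    ptab = _pvalue_table(nc, nh)
    sig_tab = ptab < alpha
    pres = (sm.states[bins] == state).astype(np.int64)  # (n_test, n_samples)
    # case-presence count under every labeling, via one matrix product
    lab_mask = np.zeros((L, n), dtype=np.int64)
    for li, combo in enumerate(labelings):
        lab_mask[li, list(combo)] = 1
    a_perm = pres @ lab_mask.T  # (n_test, L)
    total = pres.sum(axis=1)  # a + b is labeling-invariant
    b_perm = total[:, None] - a_perm
    counts = sig_tab[a_perm, b_perm].sum(axis=0)  # per labeling

    obs_case = pres[:, sm.case_idx].sum(axis=1)
    obs_ctrl = pres[:, sm.control_idx].sum(axis=1)
    p_obs = ptab[obs_case, obs_ctrl] if len(bins) else np.array([])
    k_obs = int(sig_tab[obs_case, obs_ctrl].sum()) if len(bins) else 0
    if k_obs == 0:
        p_emp = 1.0
    else:
        p_emp = (1 + int((counts > k_obs).sum())) / L

    bin_table = pd.DataFrame(
        {
            "bin": bins,
            "chrom": sm.bins["chrom"].to_numpy()[bins],
            "start": sm.bins["start"].to_numpy()[bins],
            "end": sm.bins["end"].to_numpy()[bins],
            "state": state,
            "case_present": obs_case,
            "control_present": obs_ctrl,
            "fisher_p": p_obs,
            "significant": p_obs < alpha if len(bins) else [],
        }
    )
    return PermutationResult(state, k_obs, counts, p_emp, L, bin_table)


def differential_states(sm: StateMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Permutation test for every state; one summary row per state.

    Returns the per-state observed significant-bin count and empirical p,
    sorted by empirical p then state.
    """
    rows = []
    for state in range(1, sm.n_states + 1):
        res = permutation_state_test(sm, state, alpha=alpha)
        rows.append(
            {
                "state": state,
                "n_bins_tested": len(res.bins),
                "k_obs": res.k_obs,
                "empirical_p": res.empirical_p,
                "n_labelings": res.n_labelings,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["empirical_p", "state"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# State transitions between groups
# ---------------------------------------------------------------------------


def group_consensus(sm: StateMatrix, group: str) -> np.ndarray:
    """Per-bin modal state within a group; ties resolve to the smaller
    state index."""
    idx = sm.case_idx if group == "case" else sm.control_idx
    sub = sm.states[:, idx]
    counts = np.zeros((sm.n_bins, sm.n_states), dtype=np.int64)
    for j in range(sub.shape[1]):
        counts[np.arange(sm.n_bins), sub[:, j] - 1] += 1
    return counts.argmax(axis=1) + 1  # argmax takes the first (smallest) on ties


def transition_table(sm: StateMatrix) -> pd.DataFrame:
    """Cross-tabulation of control-consensus vs case-consensus states.

    Rows are control states, columns case states; off-diagonal mass shows
    which state switches dominate between groups.
    """
    ctrl = group_consensus(sm, "control")
    case = group_consensus(sm, "case")
    tab = np.zeros((sm.n_states, sm.n_states), dtype=np.int64)
    np.add.at(tab, (ctrl - 1, case - 1), 1)
    labels = [f"E{s}" for s in range(1, sm.n_states + 1)]
    return pd.DataFrame(tab, index=labels, columns=labels)
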