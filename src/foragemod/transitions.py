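"""Module-sequence dynamics: transition matrices and stationary tests.

Each mouse's excursions, ordered by start time and restricted to
module-labeled trips, form a token sequence. One-step transition counts
are accumulated within-mouse (never across mice) and aggregated per
group. The long-run behavioral repertoire of a group is its transition
chain's stationary distribution; genotype differences are tested by the
Euclidean distance between stationary distributions against a null that
permutes whole mouse sequences between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import fisher_exact_rxc

__all__ = ["TransitionModel", "EmptyModelError", "build_transition_matrix",
           "transition_dependence_test", "stationary_distribution",
           "genotype_distance_permutation_test", "sequences_from_labels"]

DEFAULT_SMOOTHING = 1e-6


class EmptyModelError(ValueError):
    pass


@dataclass
class TransitionModel:
    states: list[str]
    counts: pd.DataFrame      # state x state transition counts
    P: pd.DataFrame           # row-stochastic transition probabilities
    pi: pd.Series             # stationary distribution
    smoothing: float = DEFAULT_SMOOTHING

    @property
    def n_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())


def sequences_from_labels(labels: dict[str, str],
                          excursion_index: pd.DataFrame,
                          drop_nonmodular: bool = True) -> dict[int, list[str]]:
    """Per-mouse module token sequences ordered by excursion start time.

    Non-modular excursions are removed and the sequence re-linked (the
    default), or kept as break markers with ``drop_nonmodular=False`` in
    which case tokens on either side of a non-modular trip do not pair.
    """
    from .excursions import parse_cimar

    df = excursion_index.copy()
    df["label"] = [labels.get(c, "0") for c in df["cimar"]]
    df["mouse"] = [parse_cimar(c).mouse_number for c in df["cimar"]]
    df["exc_no"] = [parse_cimar(c).excursion_number for c in df["cimar"]]
    df = df.sort_values(["mouse", "start_time_s", "exc_no"])
    out: dict[int, list[str]] = {}
    for mouse, g in df.groupby("mouse"):
        seq = []
        for lab in g["label"]:
            if lab.startswith("M"):
                seq.append(lab)
            elif not drop_nonmodular:
                seq.append("|")  # chain break marker
        out[int(mouse)] = seq
    return out


def _count_pairs(sequences: list[list[str]], states: list[str]) -> pd.DataFrame:
    idx = {s: i for i, s in enumerate(states)}
    C = np.zeros((len(states), len(states)), dtype=float)
    for seq in sequences:
        for a, b in zip(seq[:-1], seq[1:]):
            if a == "|" or b == "|":
                continue
            C[idx[a], idx[b]] += 1
    return pd.DataFrame(C, index=states, columns=states)


def build_transition_matrix(sequences: dict[int, list[str]] | list[list[str]],
                            states: list[str] | None = None,
                            smoothing: float = DEFAULT_SMOOTHING
                            ) -> TransitionModel:
    """Aggregate within-mouse 1-step transition counts into a chain model."""
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    if states is None:
        states = sorted({tok for s in seqs for tok in s if tok != "|"})
    if not states:
        raise EmptyModelError("no module tokens in any sequence")
    C = _count_pairs(seqs, states)
    if C.to_numpy().sum() == 0:
        raise EmptyModelError("no within-mouse module pairs")
    pi, P = stationary_distribution(C.to_numpy(), smoothing=smoothing)
    return TransitionModel(states=states, counts=C,
                           P=pd.DataFrame(P, index=states, columns=states),
                           pi=pd.Series(pi, index=states),
                           smoothing=smoothing)


def stationary_distribution(counts_or_P: np.ndarray,
                            smoothing: float = DEFAULT_SMOOTHING,
                            is_probability: bool = False
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Stationary distribution pi with pi @ P = pi, sum(pi) = 1.

    Count input gets ``smoothing`` added to every cell before row
    normalization, guaranteeing irreducibility and a unique pi. Solved as
    the null space of (P^T - I) with the normalization constraint, which
    is exact to machine precision for small chains.
    """
    A = np.asarray(counts_or_P, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("square matrix required")
    n = A.shape[0]
    if is_probability:
        P = A
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of a probability matrix must sum to 1")
    else:
        C = A + smoothing
        P = C / C.sum(axis=1, keepdims=True)
    M = np.vstack([P.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return pi, P


def transition_dependence_test(counts: pd.DataFrame | np.ndarray,
                               n_draws: int = 100_000, seed: int = 0) -> float:
    """Does the next module depend on the current one?

    Exact test on the transition count matrix: fully exact for 2x2,
    Monte-Carlo exact (conditional on margins) for larger tables.
    Degenerate rows/columns (zero margins) are dropped with a warning.
    """
    tab = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    tab = np.asarray(np.round(tab), dtype=int)
    rows_ok = tab.sum(axis=1) > 0
    cols_ok = tab.sum(axis=0) > 0
    if (~rows_ok).any() or (~cols_ok).any():
        warnings.warn("dropping zero-margin rows/columns from transition table")
    tab = tab[rows_ok][:, cols_ok]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("dependence test undefined: fewer than 2 nonzero "
                         "rows or columns")
    return fisher_exact_rxc(tab, n_draws=n_draws, seed=seed)


def genotype_distance_permutation_test(sequences_a: dict[int, list[str]],
                                       sequences_b: dict[int, list[str]],
                                       n_perm: int = 10_000, seed: int = 0,
                                       smoothing: float = DEFAULT_SMOOTHING
                                       ) -> tuple[float, float]:
    """Stationary-distribution distance between groups vs a mouse-permutation null.

    d_obs is the Euclidean distance between the two groups' stationary
    distributions (common state space). The null reassigns whole
    per-mouse sequences to the two groups (sizes preserved) and
    recomputes both chains and their distance each permutation;
    p = (1 + #{d_null >= d_obs}) / (1 + n_perm). Permutations yielding a
    group with no module pairs are resampled from scratch and counted
    with a warning.
    """
    states = sorted({tok for seqs in (sequences_a, sequences_b)
                     for s in seqs.values() for tok in s if tok != "|"})
    if not states:
        raise EmptyModelError("no module tokens in either group")
    seqs_a = list(sequences_a.values())
    seqs_b = list(sequences_b.values())

    def dist(sa: list[list[str]], sb: list[list[str]]) -> float | None:
        Ca = _count_pairs(sa, states).to_numpy()
        Cb = _count_pairs(sb, states).to_numpy()
        if Ca.sum() == 0 or Cb.sum() == 0:
            return None
        pa, _ = stationary_distribution(Ca, smoothing=smoothing)
        pb, _ = stationary_distribution(Cb, smoothing=smoothing)
        return float(np.linalg.norm(pa - pb))

    d_obs = dist(seqs_a, seqs_b)
    if d_obs is None:
        raise EmptyModelError("a group has no within-mouse module pairs")
    rng = np.random.default_rng(seed)
    pool = seqs_a + seqs_b
    na = len(seqs_a)
    exceed = 0
    resampled = 0
    for _ in range(n_perm):
        d = None
        while d is None:
            perm = rng.permutation(len(pool))
            d = dist([pool[i] for i in perm[:na]],
                     [pool[i] for i in perm[na:]])
            if d is None:
                resampled += 1
        if d >= d_obs - 1e-15:
            exceed += 1
    if resampled:
        warnings.warn(f"resampled {resampled} degenerate permutations")
    p = (1 + exceed) / (1 + n_perm)
    return d_obs, float(p)
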