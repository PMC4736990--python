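"""Haplotype collapsing and sampling-completeness estimation.

Aligned plastid sequences are collapsed into haplotypes after indel
recoding: a contiguous alignment gap longer than one base is treated as
a single mutational step (one character with gap as a fifth state)
rather than as independent per-site differences. Sequences are then
grouped by exact identity of the recoded character strings.

Whether the observed number of distinct haplotypes k among n sampled
sequences exhausts the species' haplotype pool is assessed with the
Stirling probability distribution: under θ equally frequent haplotypes,

    P(k | n, θ) = θ!/(θ-k)! · S(n, k) / θ^n,

where S(n, k) is the Stirling number of the second kind. With a uniform
prior on θ over {k..θ_max} this yields a posterior over the true
haplotype number, its mean, and the probability that sampling is
complete (θ = k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .io import HaplotypeSample

log = logging.getLogger("rguc")

__all__ = [
    "DixonResult",
    "collapse_haplotypes",
    "recode_gaps",
    "n_coded_differences",
    "stirling2_log",
    "dixon_completeness",
]

GAP = "-"
VALID_STATES = set("ACGTacgt") | {GAP}


@dataclass(frozen=True)
class DixonResult:
    """Posterior over the true haplotype number θ.

    ``posterior[i]`` is the mass at θ = k + i; ``p_complete`` is the
    posterior probability that every haplotype has been sampled (θ = k).
    """

    n: int
    k: int
    theta_max: int
    posterior: np.ndarray
    posterior_mean: float
    p_complete: float

    def __post_init__(self) -> None:
        if not np.isclose(self.posterior.sum(), 1.0):
            raise ValueError("posterior does not sum to 1")
        if self.posterior_mean < self.k - 1e-9:
            raise ValueError("posterior mean below observed haplotype count")


# ---------------------------------------------------------------------------
# gap recoding and collapsing
# ---------------------------------------------------------------------------

def recode_gaps(seq: str) -> tuple:
    """Recode one aligned sequence: each gap run longer than 1 bp becomes
    a single indel token carrying the run's span; single-base gaps stay a
    fifth character state.
    """
    out: list = []
    i, L = 0, len(seq)
    while i < L:
        c = seq[i]
        if c == GAP:
            j = i
            while j < L and seq[j] == GAP:
                j += 1
            if j - i > 1:
                out.append(("indel", i, j))
            else:
                out.append(GAP)
            i = j
        else:
            out.append(c.upper())
            i += 1
    return tuple(out)


def n_coded_differences(a: str, b: str) -> int:
    """Count differences between two aligned sequences after gap recoding.

    Walks the alignment columns; a multi-base gap run counts as one
    difference against whatever the other sequence holds over that span.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    ka, kb = recode_gaps(a), recode_gaps(b)

    def spans(tokens):
        # map each token to its (start, end) alignment span
        out, pos = [], 0
        for t in tokens:
            if isinstance(t, tuple):
                out.append((t[1], t[2], t))
                pos = t[2]
            else:
                out.append((pos, pos + 1, t))
                pos += 1
        return out

    sa, sb = spans(ka), spans(kb)
    diffs, ia, ib = 0, 0, 0
    counted: set[tuple[int, int]] = set()
    while ia < len(sa) and ib < len(sb):
        a0, a1, ta = sa[ia]
        b0, b1, tb = sb[ib]
        if a1 <= b0:
            ia += 1
            continue
        if b1 <= a0:
            ib += 1
            continue
        if (a0, a1) == (b0, b1):
            if ta != tb:
                diffs += 1
            ia += 1
            ib += 1
        else:
            # overlapping but unequal spans: one coded difference per
            # indel event involved, counted once
            key = (min(a0, b0), max(a1, b1))
            if key not in counted:
                counted.add(key)
                diffs += 1
            if a1 <= b1:
                ia += 1
            if b1 <= a1:
                ib += 1
    return diffs


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def collapse_haplotypes(
    sequences: Mapping[str, str] | str | Path,
    pop_of_sequence: Mapping[str, str] | None = None,
    ambiguity: str = "error",
) -> tuple[HaplotypeSample, dict[str, str], dict[str, dict[str, int]]]:
    """Collapse aligned sequences into haplotypes.

    Accepts a mapping id -> aligned sequence or a FASTA path. Returns
    ``(sample, haplotype_of_sequence, table)`` where ``table`` maps
    population -> {haplotype label: count} (all sequences fall into one
    pseudo-population when no mapping is given). Haplotype labels are
    roman numerals in order of first appearance.

    ``ambiguity='error'`` rejects non-ACGT/- states; ``'distinct'``
    keeps them as extra character states.
    """
    if not isinstance(sequences, Mapping):
        sequences = _read_fasta(sequences)
    if not sequences:
        raise ValueError("no sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    if ambiguity == "error":
        for sid, s in sequences.items():
            bad = set(s) - VALID_STATES
            if bad:
                raise ValueError(f"ambiguity codes {sorted(bad)} in {sid!r}")

    keys: dict[str, tuple] = {sid: recode_gaps(s) for sid, s in sequences.items()}
    label_of_key: dict[tuple, str] = {}
    hap_of_seq: dict[str, str] = {}
    for sid in sequences:
        key = keys[sid]
        if key not in label_of_key:
            label_of_key[key] = _roman(len(label_of_key) + 1)
        hap_of_seq[sid] = label_of_key[key]

    table: dict[str, dict[str, int]] = {}
    for sid, hap in hap_of_seq.items():
        pop = pop_of_sequence.get(sid, "all") if pop_of_sequence else "all"
        table.setdefault(pop, {})
        table[pop][hap] = table[pop].get(hap, 0) + 1

    counts: dict[str, int] = {}
    for hap in hap_of_seq.values():
        counts[hap] = counts.get(hap, 0) + 1
    ordered = [counts[_roman(i + 1)] for i in range(len(label_of_key))]
    sample = HaplotypeSample(n=len(sequences), k=len(label_of_key), counts=tuple(ordered))
    return sample, hap_of_seq, table


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


# ---------------------------------------------------------------------------
# Stirling machinery
# ---------------------------------------------------------------------------

def stirling2_log(n: int, k: int) -> float:
    """log S(n, k), exact in log space via the standard recurrence.

    S(n, k) = k·S(n-1, k) + S(n-1, k-1); stable for n of a few hundred.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    return _stirling2_log_row(n, k)[k]


def _stirling2_log_row(n: int, kmax: int) -> np.ndarray:
    NEG = -np.inf
    prev = np.full(kmax + 1, NEG)
    prev[0] = 0.0  # S(0,0) = 1
    for m in range(1, n + 1):
        cur = np.full(kmax + 1, NEG)
        top = min(m, kmax)
        for k in range(1, top + 1):
            with_k = np.log(k) + prev[k] if prev[k] > NEG else NEG
            cur[k] = np.logaddexp(with_k, prev[k - 1])
        prev = cur
    return prev


def stirling_log_likelihood(n: int, k: int, theta: int) -> float:
    """log P(k | n, θ) = log[θ!/(θ-k)! · S(n,k) / θ^n] (equal frequencies)."""
    if theta < k:
        return -np.inf
    return (
        gammaln(theta + 1)
        - gammaln(theta - k + 1)
        + stirling2_log(n, k)
        - n * np.log(theta)
    )


def dixon_completeness(
    sample: HaplotypeSample,
    theta_max: int = 100,
    prior: Sequence[float] | None = None,
) -> DixonResult:
    """Posterior over the true haplotype number θ given n draws, k distinct.

    Uniform prior on θ ∈ {k..theta_max} by default; a custom prior of
    the same length may be supplied. The result is checked for
    insensitivity to theta_max (tail mass beyond ~3k must be negligible
    unless the data genuinely push θ high).
    """
    n, k = sample.n, sample.k
    if theta_max < k:
        raise ValueError("theta_max must be >= k")
    if n == 1 and k == 1:
        log.warning("n = k = 1: the likelihood is flat; data carry no information")
    thetas = np.arange(k, theta_max + 1)
    ls_nk = _stirling2_log_row(n, k)[k]
    loglik = gammaln(thetas + 1) - gammaln(thetas - k + 1) + ls_nk - n * np.log(thetas)
    if prior is not None:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != thetas.shape or (prior < 0).any() or prior.sum() == 0:
            raise ValueError("prior must be nonnegative over {k..theta_max}")
        loglik = loglik + np.log(np.where(prior > 0, prior, np.nan))
        loglik = np.nan_to_num(loglik, nan=-np.inf)
    w = np.exp(loglik - loglik.max())
    posterior = w / w.sum()
    mean = float(posterior @ thetas)
    tail = float(posterior[thetas > 3 * k].sum()) if theta_max > 3 * k else 0.0
    if tail > 1e-6 and posterior.argmax() < len(posterior) - 1:
        log.warning("posterior tail mass %.3g beyond 3k; consider raising theta_max", tail)
    if sample.counts is not None:
        c = np.array(sample.counts, dtype=float)
        if c.max() / c.sum() > 0.5 and k > 1:
            log.warning(
                "haplotype counts are highly skewed (max share %.2f); the "
                "equal-frequency assumption is optimistic", c.max() / c.sum()
            )
    return DixonResult(
        n=n,
        k=k,
        theta_max=theta_max,
        posterior=posterior,
        posterior_mean=mean,
        p_complete=float(posterior[0]),
    )
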