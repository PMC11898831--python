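"""Synthetic recommendation panels with controllable agreement structure.

The generative model mirrors the shape of the study data: each case has a
latent consensus option ``c`` drawn from ``consensus_distribution``; each
rater's primary option equals ``c`` with that rater's adherence probability
θ, otherwise is uniform over the remaining vocabulary; after the primary,
distractor options are appended one at a time, each with probability λ
(``extra_rate``), drawn uniformly without replacement from the unused part
of the vocabulary (a truncated-geometric tail).

Defaults emulate the study conditions: 22 cases, the 11-code vocabulary,
3 reference + 5 candidate raters, θ = 0.5 (mid-range agreement comparable
to the moderate concordance observed in the study) and λ = 0.3 (mean cell
size ≈ 1.4, within the 1.0–1.9 options-per-case range the raters produced).

``expected_union_accuracy`` gives the generator's own closed-form hit
probability in the λ = 0 (singleton) regime, for parameter-recovery checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import CaseRecord, Panel, Recommendation


@dataclass
class SyntheticPanelConfig:
    """Generator configuration; defaults emulate the study panel's shape."""

    n_cases: int = 22
    vocabulary: tuple[int, ...] = tuple(range(1, 12))
    n_reference: int = 3
    n_candidate: int = 5
    adherence: float | Sequence[float] = 0.5
    extra_rate: float = 0.3
    consensus_distribution: Mapping[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.vocabulary = tuple(dict.fromkeys(self.vocabulary))
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if self.n_reference < 0 or self.n_candidate < 0:
            raise ValueError("roster sizes must be non-negative")
        if self.n_reference + self.n_candidate < 1:
            raise ValueError("at least one rater is required")
        thetas = self.adherence_per_rater()
        for theta in thetas:
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"adherence {theta} outside [0, 1]")
        if any(t < 1.0 for t in thetas) and len(self.vocabulary) < 2:
            raise ValueError(
                "vocabulary of size 1 cannot support adherence below 1"
            )
        if not 0.0 <= self.extra_rate < 1.0:
            raise ValueError("extra_rate must lie in [0, 1)")
        if self.consensus_distribution is not None:
            dist = dict(self.consensus_distribution)
            if set(dist) - set(self.vocabulary):
                raise ValueError("consensus_distribution has out-of-vocabulary codes")
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or not np.isclose(total, 1.0):
                raise ValueError("consensus_distribution must be a distribution")

    @property
    def n_raters(self) -> int:
        return self.n_reference + self.n_candidate

    @property
    def rater_ids(self) -> tuple[str, ...]:
        refs = tuple(f"ref{i + 1}" for i in range(self.n_reference))
        cands = tuple(f"cand{i + 1}" for i in range(self.n_candidate))
        return refs + cands

    def adherence_per_rater(self) -> tuple[float, ...]:
        """θ per rater, references first; a scalar is broadcast to all raters."""
        if isinstance(self.adherence, (int, float)):
            return (float(self.adherence),) * self.n_raters
        thetas = tuple(float(t) for t in self.adherence)
        if len(thetas) != self.n_raters:
            raise ValueError(
                f"adherence has {len(thetas)} entries for {self.n_raters} raters"
            )
        return thetas

    def consensus_probs(self) -> tuple[tuple[int, ...], tuple[float, ...]]:
        if self.consensus_distribution is None:
            v = len(self.vocabulary)
            return self.vocabulary, (1.0 / v,) * v
        dist = dict(self.consensus_distribution)
        codes = tuple(c for c in self.vocabulary if dist.get(c, 0.0) > 0)
        probs = np.array([dist[c] for c in codes], dtype=float)
        probs = probs / probs.sum()
        return codes, tuple(probs)


def generate_panel(config: SyntheticPanelConfig) -> Panel:
    """Draw one panel from the generator; deterministic under a fixed seed.

    A single pseudo-random stream (seeded from ``config.seed``) drives the
    whole panel; cases are generated in order, raters in roster order
    (references first) within each case.
    """
    rng = np.random.default_rng(config.seed)
    thetas = config.adherence_per_rater()
    rater_ids = config.rater_ids
    codes, probs = config.consensus_probs()
    vocab = config.vocabulary
    cases: list[CaseRecord] = []
    for case_idx in range(config.n_cases):
        consensus = codes[rng.choice(len(codes), p=probs)]
        ratings: dict[str, Recommendation] = {}
        for rater, theta in zip(rater_ids, thetas):
            if rng.random() < theta:
                primary = consensus
            else:
                others = [c for c in vocab if c != consensus]
                primary = others[rng.integers(len(others))]
            chosen = [primary]
            remaining = [c for c in vocab if c != primary]
            while remaining and rng.random() < config.extra_rate:
                pick = rng.integers(len(remaining))
                chosen.append(remaining.pop(pick))
            ratings[rater] = Recommendation(tuple(chosen))
        cases.append(CaseRecord(case_idx + 1, ratings))
    return Panel(
        tuple(cases),
        candidate_raters=rater_ids[config.n_reference :],
        reference_raters=rater_ids[: config.n_reference],
    )


def expected_union_accuracy(
    config: SyntheticPanelConfig, candidate_index: int = 0
) -> float:
    """Closed-form union-hit probability for one candidate, λ = 0 regime.

    Enumerates the latent consensus option and the candidate's primary
    label; given both, each reference independently covers the label with a
    known probability, so the union-hit chance is one minus the product of
    the misses. Only valid when ``extra_rate`` is zero (all cells are
    singletons).
    """
    if config.extra_rate != 0.0:
        raise ValueError("closed form requires extra_rate = 0")
    if config.n_candidate < 1:
        raise ValueError("config has no candidate raters")
    if not 0 <= candidate_index < config.n_candidate:
        raise ValueError(f"candidate index {candidate_index} out of range")
    if config.n_reference < 1:
        raise ValueError("config has no reference raters")
    thetas = config.adherence_per_rater()
    ref_thetas = thetas[: config.n_reference]
    theta_cand = thetas[config.n_reference + candidate_index]
    vocab = config.vocabulary
    v = len(vocab)
    codes, probs = config.consensus_probs()
    total = 0.0
    for consensus, p_c in zip(codes, probs):
        for label in vocab:
            if label == consensus:
                p_label = theta_cand
            elif v > 1:
                p_label = (1.0 - theta_cand) / (v - 1)
            else:
                p_label = 0.0
            if p_label == 0.0:
                continue
            miss = 1.0
            for theta_ref in ref_thetas:
                if label == consensus:
                    p_cover = theta_ref
                elif v > 1:
                    p_cover = (1.0 - theta_ref) / (v - 1)
                else:
                    p_cover = 0.0
                miss *= 1.0 - p_cover
            total += p_c * p_label * (1.0 - miss)
    return total
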