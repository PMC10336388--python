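"""Volunteer's dilemma models of predator inspection.

In the volunteer's dilemma a single volunteer suffices to produce a public
good (here: the information gained by inspecting a predator) for the whole
group.  Payoff convention: with ``k`` volunteers in a group of ``n``, every
member receives the benefit ``b_k`` provided ``k >= 1`` (the non-production
cost is the forgone benefit), and each volunteer additionally pays a cost.
At the mixed evolutionarily stable strategy (ESS) each individual
volunteers with the probability ``p`` that makes volunteering and defecting
payoff-equivalent, given the other ``n - 1`` members volunteer
independently with the same ``p``.

Variants:

- ``baseline``: constant benefit ``b`` and cost ``c``; closed form
  ``p = 1 - (c/b)^(1/(n-1))``.  Both ``p`` and the probability that anyone
  volunteers decline with ``n`` — the group size paradox.
- ``groupsize_cost``: the volunteering cost declines with group size,
  ``c(n) = c * exp(-cost_decay * (n - 2))``.  A power-law decline cannot
  overturn the paradox (the 1/(n-1) exponent in the ESS always wins), but
  an exponential decline with ``cost_decay > ln(b/c)`` makes the
  volunteering probability increase with group size.
- ``shared_cost``: the cost is split among the realized volunteers,
  ``c / k``; sharing softens but does not reverse the decline of ``p``
  with ``n``.
- ``synergy``: the benefit grows with the number of volunteers,
  ``b_k = b * (1 + synergy_slope * (k - 1)**synergy_power)``.  Linear
  synergy (power 1) only rescales the dilemma; accelerating synergy
  (default power 2) makes volunteering strictly dominant in large groups
  while small groups retain an interior mixed ESS, so individuals in
  larger groups volunteer more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom

from .errors import NoDilemmaError

__all__ = ["VDGame", "ESSResult", "solve_ess", "predict_group_size_curve", "simulate_vd"]

_VARIANTS = ("baseline", "shared_cost", "groupsize_cost", "synergy")


@dataclass(frozen=True)
class VDGame:
    """A volunteer's dilemma parameterization.

    n : group size (>= 2); cost_volunteer : c; benefit : b (> c);
    variant : payoff structure; variant_params : e.g. ``cost_exponent``
    (groupsize_cost) or ``synergy_slope`` (synergy).
    """

    n: int
    cost_volunteer: float
    benefit: float
    variant: str = "baseline"
    variant_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2 or int(self.n) != self.n:
            raise ValueError(f"n must be an integer >= 2, got {self.n}")
        if self.cost_volunteer <= 0:
            raise ValueError("cost_volunteer must be positive")
        if self.cost_volunteer >= self.benefit:
            raise NoDilemmaError(
                f"no dilemma: cost {self.cost_volunteer} >= benefit {self.benefit}"
            )
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")

    def benefit_k(self, k: np.ndarray) -> np.ndarray:
        """Benefit to each group member when k >= 1 members volunteer."""
        k = np.asarray(k, dtype=float)
        if self.variant == "synergy":
            s = float(self.variant_params.get("synergy_slope", 0.05))
            power = float(self.variant_params.get("synergy_power", 2.0))
            return self.benefit * (1.0 + s * (k - 1.0) ** power)
        return np.full_like(k, self.benefit)

    def cost_k(self, k: np.ndarray) -> np.ndarray:
        """Cost paid by each volunteer when k members volunteer in total."""
        k = np.asarray(k, dtype=float)
        if self.variant == "shared_cost":
            return self.cost_volunteer / k
        if self.variant == "groupsize_cost":
            decay = float(self.variant_params.get("cost_decay", 1.0))
            return np.full_like(
                k, self.cost_volunteer * np.exp(-decay * (self.n - 2))
            )
        return np.full_like(k, self.cost_volunteer)


@dataclass(frozen=True)
class ESSResult:
    """Solved mixed ESS: per-individual volunteering probability, the
    probability that the public good is produced, and n * p."""

    p_volunteer: float
    p_good: float
    expected_volunteers: float


def payoff_gap(game: VDGame, p: float) -> float:
    """E[payoff | volunteer] - E[payoff | defect] when the other n-1
    members volunteer independently with probability p.

    The number of co-volunteers K is Binomial(n-1, p); a volunteer
    experiences k = K + 1 volunteers, a defector k = K and earns the
    benefit only when K >= 1.
    """
    n = game.n
    k_others = np.arange(n)
    w = binom.pmf(k_others, n - 1, p)
    volunteer = float(np.sum(w * (game.benefit_k(k_others + 1) - game.cost_k(k_others + 1))))
    defect_benefit = game.benefit_k(k_others)
    defect_benefit = np.where(k_others >= 1, defect_benefit, 0.0)
    defect = float(np.sum(w * defect_benefit))
    return volunteer - defect


def solve_ess(game: VDGame) -> ESSResult:
    """Solve the mixed-ESS volunteering probability.

    The baseline uses the closed form ``p = 1 - (c/b)^(1/(n-1))``; variants
    root-find the indifference condition payoff_gap(p) = 0 to |gap| < 1e-10.
    Returns the degenerate p = 1 (or p = 0) when one strategy dominates.
    """
    if game.variant == "baseline":
        p = 1.0 - (game.cost_volunteer / game.benefit) ** (1.0 / (game.n - 1))
    else:
        gap0 = payoff_gap(game, 0.0)
        gap1 = payoff_gap(game, 1.0)
        if gap0 <= 0.0:
            p = 0.0
        elif gap1 >= 0.0:
            p = 1.0
        else:
            p = brentq(lambda q: payoff_gap(game, q), 0.0, 1.0, xtol=1e-14, rtol=1e-15)
            assert abs(payoff_gap(game, p)) < 1e-10
    return ESSResult(
        p_volunteer=float(p),
        p_good=float(1.0 - (1.0 - p) ** game.n),
        expected_volunteers=float(game.n * p),
    )


def predict_group_size_curve(
    variant: str,
    params: dict | None,
    n_range,
    cost_volunteer: float = 0.3,
    benefit: float = 1.0,
) -> pd.DataFrame:
    """ESS solutions over a range of group sizes.

    Returns a table (n, p_volunteer, p_good, expected_volunteers) with
    monotonicity diagnostics: the sign of the successive difference in
    p_volunteer and p_good (NaN for the first row).
    """
    n_range = sorted(int(n) for n in n_range)
    if any(n < 2 or n > 50 for n in n_range):
        raise ValueError("group sizes must lie in 2..50")
    rows = []
    for n in n_range:
        res = solve_ess(
            VDGame(n=n, cost_volunteer=cost_volunteer, benefit=benefit,
                   variant=variant, variant_params=params or {})
        )
        rows.append(
            {"n": n, "p_volunteer": res.p_volunteer, "p_good": res.p_good,
             "expected_volunteers": res.expected_volunteers}
        )
    out = pd.DataFrame(rows)
    out["dp_volunteer_sign"] = np.sign(out["p_volunteer"].diff())
    out["dp_good_sign"] = np.sign(out["p_good"].diff())
    return out


def simulate_vd(
    game: VDGame, p: float, reps: int, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Monte-Carlo check of the analytic solution.

    Each rep draws n independent Bernoulli(p) volunteering decisions;
    returns (empirical probability that >= 1 volunteers, mean volunteers).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    volunteers = rng.binomial(game.n, p, size=reps)
    return float(np.mean(volunteers >= 1)), float(volunteers.mean())
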