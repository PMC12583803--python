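"""Per-cycle transition kernels for the BCVA Markov model.

Movement between BCVA bands is limited to one state per 3-monthly cycle.
The no-treatment kernel uses the recalibrated natural-history probabilities
(gain 3.5%, lose 4.5% per cycle); treatment kernels are derived from the
12-month mean BCVA difference by assuming individual BCVA change is
normally distributed and reading off the probabilities of crossing the
+/-5-letter band boundary. Death is embedded as a competing hazard from
age- and sex-specific life tables scaled by the diabetes hazard ratio.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .states import DEATH, N_ALIVE, N_STATES

__all__ = [
    "TransitionMatrix",
    "LifeTable",
    "build_natural_history_matrix",
    "build_band_matrix",
    "maintenance_matrix",
    "logmar_md_to_letters",
    "treatment_transition_probs",
    "cycle_death_probability",
    "assemble_matrix",
]

_ROW_TOL = 1e-12

#: ETDRS convention: 0.1 logMAR corresponds to 5 letters, i.e. 1 letter
#: = 0.02 logMAR; a negative logMAR difference is a vision gain.
LETTERS_PER_LOGMAR = -50.0

#: Band half-width in letters: states are 10 letters wide, so a move of
#: at least 5 letters (half a band, "the average eye") changes state.
BAND_THRESHOLD_LETTERS = 5.0


@dataclass
class TransitionMatrix:
    """A 9x9 per-cycle kernel (from-state rows, to-state columns)."""

    entries: np.ndarray
    label: str = ""
    cycle_length_months: int = 3

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 9x9")

    def validate(self) -> None:
        """Raise if the kernel violates its structural invariants."""
        m = self.entries
        if (m < -_ROW_TOL).any() or (m > 1 + _ROW_TOL).any():
            raise ValueError(f"{self.label}: entries outside [0, 1]")
        rows = m.sum(axis=1)
        if np.abs(rows - 1.0).max() > _ROW_TOL:
            raise ValueError(f"{self.label}: rows do not sum to 1 "
                             f"(max dev {np.abs(rows - 1).max():.3e})")
        if not (m[DEATH, DEATH] == 1.0 and m[DEATH, :DEATH].sum() == 0.0):
            raise ValueError(f"{self.label}: death state is not absorbing")
        # alive-to-alive movement limited to one band per cycle
        alive = m[:N_ALIVE, :N_ALIVE]
        for i in range(N_ALIVE):
            for j in range(N_ALIVE):
                if abs(i - j) > 1 and alive[i, j] > _ROW_TOL:
                    raise ValueError(f"{self.label}: mass {alive[i, j]:.3e} on "
                                     f"a {abs(i - j)}-band move ({i}->{j})")


def build_band_matrix(p_gain: float, p_lose: float,
                      label: str = "") -> TransitionMatrix:
    """Tridiagonal alive-conditional kernel with per-cycle probabilities of
    moving one band toward better (``p_gain``) or worse (``p_lose``) vision.

    Boundary rows fold the impossible move back into "stay". The death row
    is absorbing; alive rows route no mass to death (mortality is embedded
    afterwards by :func:`assemble_matrix`).
    """
    if not (0 <= p_gain <= 1 and 0 <= p_lose <= 1):
        raise ValueError("p_gain and p_lose must lie in [0, 1]")
    if p_gain + p_lose > 1:
        raise ValueError(f"p_gain + p_lose = {p_gain + p_lose} exceeds 1")
    m = np.zeros((N_STATES, N_STATES))
    stay = 1.0 - p_gain - p_lose
    for i in range(N_ALIVE):
        m[i, i] = stay
        if i > 0:
            m[i, i - 1] = p_gain     # toward better vision (lower index)
        else:
            m[i, i] += p_gain        # already at the best band
        if i < N_ALIVE - 1:
            m[i, i + 1] = p_lose     # toward worse vision
        else:
            m[i, i] += p_lose        # already at the worst band
    m[DEATH, DEATH] = 1.0
    return TransitionMatrix(m, label=label)


def build_natural_history_matrix(p_gain: float = 0.035,
                                 p_lose: float = 0.045) -> TransitionMatrix:
    """Natural-history kernel (recalibrated WESDR/RESTORE probabilities)."""
    return build_band_matrix(p_gain, p_lose, label="natural history")


def maintenance_matrix() -> TransitionMatrix:
    """Kernel that holds achieved BCVA (identity among alive states)."""
    return build_band_matrix(0.0, 0.0, label="maintenance")


def logmar_md_to_letters(md_logmar: float) -> float:
    """Convert a logMAR mean difference to ETDRS letters (gains positive)."""
    return LETTERS_PER_LOGMAR * md_logmar


def treatment_transition_probs(md_logmar: float, sigma_letters_cycle: float,
                               cycle_fraction: float) -> tuple[float, float]:
    """Per-cycle (p_gain, p_lose) implied by a normal model of BCVA change.

    The 12-month mean difference is scaled to the cycle (mean
    ``letters * cycle_fraction``); with per-cycle SD ``sigma_letters_cycle``
    the probabilities of gaining/losing one band are the normal tail masses
    beyond +/-5 letters.
    """
    if sigma_letters_cycle <= 0:
        raise ValueError("sigma_letters_cycle must be positive")
    if not 0 < cycle_fraction <= 1:
        raise ValueError("cycle_fraction must lie in (0, 1]")
    mu_c = logmar_md_to_letters(md_logmar) * cycle_fraction
    p_gain = float(norm.sf(BAND_THRESHOLD_LETTERS, loc=mu_c,
                           scale=sigma_letters_cycle))
    p_lose = float(norm.cdf(-BAND_THRESHOLD_LETTERS, loc=mu_c,
                            scale=sigma_letters_cycle))
    return p_gain, p_lose


@dataclass
class LifeTable:
    """Annual probabilities of death by integer age and sex."""

    ages: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        for qx in (self.qx_male, self.qx_female):
            if (qx < 0).any() or (qx > 1).any():
                raise ValueError("life-table qx outside [0, 1]")
            if qx[-1] != 1.0:
                raise ValueError("life table must close out (qx = 1 at max age)")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def qx(self, age: float, male_fraction: float) -> float:
        """Sex-mixed annual death probability at the integer age floor."""
        a = min(int(math.floor(age)), self.max_age)
        if a < self.ages[0]:
            raise ValueError(f"age {age} below life-table range")
        i = a - int(self.ages[0])
        return (male_fraction * self.qx_male[i]
                + (1.0 - male_fraction) * self.qx_female[i])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["age", "qx_male", "qx_female"])
            for a, qm, qf in zip(self.ages, self.qx_male, self.qx_female):
                w.writerow([int(a), repr(float(qm)), repr(float(qf))])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        ages, qm, qf = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ages.append(int(row["age"]))
                qm.append(float(row["qx_male"]))
                qf.append(float(row["qx_female"]))
        return cls(np.array(ages), np.array(qm), np.array(qf), source=str(path))


def cycle_death_probability(age: float, male_fraction: float,
                            life_table: LifeTable, hr: float,
                            cycle_fraction: float) -> float:
    """Per-cycle death probability with a hazard-scale hazard ratio.

    The annual sex-mixed probability is converted to a hazard, scaled by
    the diabetes hazard ratio and the cycle length, and converted back:
    ``1 - exp(-hr * cycle_fraction * (-ln(1 - qx)))``. At the terminal age
    (qx = 1) the cycle probability is 1 regardless of scaling.
    """
    q = life_table.qx(age, male_fraction)
    if q >= 1.0:
        return 1.0
    if q == 0.0:
        return 0.0
    return 1.0 - math.exp(-hr * cycle_fraction * (-math.log1p(-q)))


def assemble_matrix(alive_kernel: TransitionMatrix,
                    p_death: float) -> TransitionMatrix:
    """Embed a per-cycle death probability into an alive-conditional kernel.

    Death is removed first as a competing hazard: alive rows are scaled by
    ``1 - p_death`` with the removed mass routed to the death column.
    """
    if not 0.0 <= p_death <= 1.0:
        raise ValueError("p_death must lie in [0, 1]")
    m = alive_kernel.entries.copy()
    m[:N_ALIVE, :] *= (1.0 - p_death)
    m[:N_ALIVE, DEATH] += p_death
    m[DEATH, :] = 0.0
    m[DEATH, DEATH] = 1.0
    return TransitionMatrix(m, label=f"{alive_kernel.label}+mortality",
                            cycle_length_months=alive_kernel.cycle_length_months)
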