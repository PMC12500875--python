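"""Synthetic biofilter observation tables with a known monomial ground truth.

The generator emulates the structure of multi-study biofilter monitoring
data: nine positive-valued dimensional variables, sparse sampling, and
study provenance.  Independent variables are drawn log-uniformly over
plausible lab-to-full-scale ranges; the effluent carbon concentration is
then constructed from the dimensionless monomial law

    EC_org / IC_org = exp(beta0) * prod_i pi_i^beta_i * exp(eps),

with multiplicative log-normal noise ``eps ~ N(0, sigma^2)``.  Because
the dependent variable is generated *from* the pi-groups, every
downstream stage (feature construction, model fitting, evaluation) can be
tested against exact known truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import biofilter_repeating, biofilter_specs
from .dimensions import VariableSpec, construct_pi_basis, evaluate_pi

__all__ = ["DEFAULT_RANGES", "SyntheticConfig", "generate"]

#: Log-uniform sampling bounds per variable, canonical units.  Chosen to
#: span lab columns through full-scale filters so the pi-groups vary over
#: several decades: pore size 0.1-2 mm, particle diameter 0.5-2 mm, bed
#: diameter 20 mm - 2 m, age 1-500 days, contact time 0.1-5 h, influent
#: carbon 1-10 g/m^3, water 278-298 K, ambient 270-305 K.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "T": (278.0, 298.0),
    "Pz": (1.0e-4, 2.0e-3),
    "A": (8.64e4, 4.32e7),
    "IC_org": (1.0, 10.0),
    "Bt": (3.6e2, 1.8e4),
    "P": (5.0e-4, 2.0e-3),
    "C_fit": (2.0e-2, 2.0),
    "t0": (270.0, 305.0),
}

#: Exponents and log-intercept of the reference monomial law used as the
#: generator default (ratios ordered Pz/C_fit, Bt/A, P/C_fit, t0/T).
DEFAULT_BETA: tuple[float, ...] = (-0.06, -0.30, 0.53, -0.09)
DEFAULT_BETA0: float = -0.07


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic generator.

    ``study_sizes`` fixes the number of rows per study (defaults mirror a
    combined three-study campaign of 175 + 26 + 116 = 317 observations);
    set it to ``None`` to assign ``n_studies`` study labels cyclically.
    """

    n_rows: int = 317
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    beta: Sequence[float] = DEFAULT_BETA
    beta0: float = DEFAULT_BETA0
    sigma: float = 0.05
    n_studies: int = 3
    study_sizes: Sequence[int] | None = (175, 26, 116)
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows <= 0:
            raise ValueError("n_rows must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_studies <= 0:
            raise ValueError("n_studies must be positive")
        for sym, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(
                    f"range for {sym!r} must satisfy 0 < lo <= hi, got ({lo}, {hi})"
                )
        if self.study_sizes is not None:
            if any(s <= 0 for s in self.study_sizes):
                raise ValueError("study_sizes must be positive")
            if sum(self.study_sizes) != self.n_rows:
                raise ValueError(
                    f"study_sizes sum {sum(self.study_sizes)} != n_rows {self.n_rows}"
                )


def generate(
    config: SyntheticConfig,
    specs: Sequence[VariableSpec] | None = None,
    repeating: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw a synthetic observation table under ``config``.

    The pi-basis is constructed from ``specs`` (biofilter defaults) and
    ``config.beta`` must supply one exponent per independent group.
    """
    config.validate()
    if specs is None:
        specs = biofilter_specs()
        if repeating is None:
            repeating = biofilter_repeating()
    basis = construct_pi_basis(specs, repeating=repeating)
    if len(config.beta) != len(basis.independent):
        raise ValueError(
            f"beta has {len(config.beta)} exponents but the system yields "
            f"{len(basis.independent)} independent pi-groups"
        )
    indep_syms = [s.symbol for s in specs if s.role == "independent"]
    dep_sym = next(s.symbol for s in specs if s.role == "dependent")
    missing = [s for s in indep_syms if s not in config.ranges]
    if missing:
        raise ValueError(f"no sampling range for variable(s) {missing}")

    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    df = pd.DataFrame(index=pd.RangeIndex(n))
    if config.study_sizes is not None:
        labels = np.repeat(
            [f"study_{i + 1}" for i in range(len(config.study_sizes))],
            list(config.study_sizes),
        )
        df["study_id"] = labels
        df["sample_time"] = np.concatenate(
            [np.arange(s, dtype=float) for s in config.study_sizes]
        )
    else:
        df["study_id"] = [f"study_{i % config.n_studies + 1}" for i in range(n)]
        df["sample_time"] = np.arange(n, dtype=float) // config.n_studies
    for sym in indep_syms:
        lo, hi = config.ranges[sym]
        df[sym] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    pi = evaluate_pi(basis, df, include_dependent=False)
    log_dep = config.beta0 + np.log(pi.to_numpy()) @ np.asarray(config.beta, float)
    if config.sigma > 0:
        log_dep = log_dep + rng.normal(0.0, config.sigma, size=n)
    # invert the dependent group (EC/IC for the biofilter system):
    # pi_dep = dep * prod(v^e)  =>  dep = pi_dep * prod(v^-e)
    scale = np.ones(n)
    for sym, e in basis.dependent.exponents.items():
        if sym != dep_sym:
            scale = scale * np.power(df[sym].to_numpy(dtype=float), -float(e))
    df[dep_sym] = np.exp(log_dep) * scale
    ordered = ["study_id", "sample_time"] + [s.symbol for s in specs]
    return df[ordered]
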