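"""Synthetic paired miRNA/mRNA data with planted star modules.

The generator emulates the structure the pipeline is designed to detect in
case/control expression cohorts:

* a small set of *driver* miRNAs whose expression is shifted in cases
  (class-dependent Gaussian, shift = ``effect_size`` standard deviations),
* for each driver, a block of target mRNAs negatively correlated with it
  (population correlation = -``regulation_strength``), mimicking miRNA
  repression of its targets,
* a large background of i.i.d. Gaussian noise features in both layers,
* class imbalance (default 66 case / 33 control, exercising the 1:2
  under-sampling path).

An optional count-scale transform (exponentiate and round) produces
non-negative pseudo-counts so the RPM/RPKM paths can be exercised.
Ground truth (driver -> target set) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_expression import ExpressionDataset, PairedOmicsDataset


@dataclass
class SyntheticConfig:
    n_case: int = 66
    n_control: int = 33
    n_driver_mirnas: int = 5
    targets_per_driver: int = 10
    n_noise_mirnas: int = 95
    n_noise_mrnas: int = 500
    effect_size: float = 2.0  # class-mean shift of drivers, in sd units
    regulation_strength: float = 0.7  # |corr| between driver and each target
    noise_sd: float = 1.0
    count_scale: bool = False  # exponentiate+round to pseudo-counts
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_driver_mirnas", "targets_per_driver",
                     "n_noise_mirnas", "n_noise_mrnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_case + self.n_control < 4:
            raise ValueError("need at least 4 samples")
        if not (0 <= self.regulation_strength <= 1):
            raise ValueError("regulation_strength must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _driver_name(i: int) -> str:
    return f"hsa-miR-sim-D{i + 1:03d}"


def _target_name(i: int, j: int) -> str:
    return f"GENE-D{i + 1:03d}-T{j + 1:02d}"


def generate(config: SyntheticConfig) -> tuple[PairedOmicsDataset, dict[str, set[str]]]:
    """Generate one paired dataset plus the planted ground truth.

    Driver profile: z = N(class_shift, noise_sd^2) with class_shift =
    effect_size * noise_sd for cases, 0 for controls.  Each target is
    -rho * z_std + sqrt(1-rho^2) * eps with z standardized by its known
    population moments, so the population driver-target correlation is
    exactly -rho (the class signal propagates into the targets through z).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    labels = np.concatenate([np.ones(config.n_case), np.zeros(config.n_control)]).astype(np.int8)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    p = config.n_case / n
    shift = config.effect_size * config.noise_sd
    pop_sd = np.sqrt(config.noise_sd**2 + shift**2 * p * (1 - p))
    pop_mean = shift * p

    mirna_rows: dict[str, np.ndarray] = {}
    mrna_rows: dict[str, np.ndarray] = {}
    truth: dict[str, set[str]] = {}
    rho = config.regulation_strength
    for i in range(config.n_driver_mirnas):
        z = rng.normal(loc=shift * labels, scale=config.noise_sd)
        mirna_rows[_driver_name(i)] = z
        z_std = (z - pop_mean) / pop_sd
        targets = set()
        for j in range(config.targets_per_driver):
            eps = rng.normal(size=n)
            name = _target_name(i, j)
            mrna_rows[name] = -rho * z_std + np.sqrt(1 - rho**2) * eps
            targets.add(name)
        truth[_driver_name(i)] = targets

    for i in range(config.n_noise_mirnas):
        mirna_rows[f"hsa-miR-sim-N{i + 1:03d}"] = rng.normal(scale=config.noise_sd, size=n)
    for i in range(config.n_noise_mrnas):
        mrna_rows[f"GENE-N{i + 1:04d}"] = rng.normal(scale=config.noise_sd, size=n)

    def _frame(rows: dict[str, np.ndarray]) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
        if config.count_scale:
            df = np.rint(np.exp2(df + 8.0)).clip(lower=0)
        return df

    paired = PairedOmicsDataset(
        ExpressionDataset(_frame(mirna_rows), "miRNA"),
        ExpressionDataset(_frame(mrna_rows), "mRNA"),
        pd.Series(labels, index=sample_ids, name="label"),
    )
    return paired, truth
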