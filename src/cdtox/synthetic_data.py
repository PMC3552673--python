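"""Synthetic microarray studies with the structure the pipeline assumes.

The generator emulates the study design being analyzed: two exposure blocks
(1 day at 0/9/27/45 uM and 13 days at 0/4.5/9/27 uM Cd2+), one array per
condition, MAS5-like positive signals with Present/Absent calls, a minority
of dose-linear responder genes per block, a configurable fraction of
responders shared (same sign) between blocks, and planted co-regulated
modules driven by a shared monotone-in-dose latent variable.  A ground-truth
table accompanies every study so parameter recovery is testable end to end.

Data model, per gene g and sample s:

    log2 signal_gs = baseline_g
                     + slope_g(block(s)) * dose_s          (responders)
                     + strength * loading_g * driver(dose_s)  (module members)
                     + Normal(0, noise_sd)

with baseline_g ~ Normal(baseline_log2_mean, baseline_log2_sd).  The module
driver is a shared latent profile (one realization per module): a monotone
dose trend mixed with a module-specific per-sample component
(``driver_jitter_sd``), standardized to unit SD across samples so
``driver_strength`` is the module effect size in log2 units, mirroring how
``slope_scale`` sizes responders.  The module-specific component is what
makes a module detectable as such: a purely dose-monotone profile is
rank-identical to a strong responder.
Signals are 2**log2 (hence strictly positive); genes in the lowest baseline
quartile draw an Absent call with probability ``absent_prob_low_expr`` per
sample, everything else is Present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import ExpressionStudy, write_annotation, write_expression

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "write_study"]

DRIVER_SHAPES = ("linear", "saturating", "random_monotone")


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the 2-block single-replicate design."""

    n_genes: int = 2000
    doses_block1: tuple[float, ...] = (0.0, 9.0, 27.0, 45.0)
    doses_block2: tuple[float, ...] = (0.0, 4.5, 9.0, 27.0)
    time_block1: float = 1.0
    time_block2: float = 13.0
    frac_pos_block1: float = 0.02
    frac_neg_block1: float = 0.02
    frac_pos_block2: float = 0.02
    frac_neg_block2: float = 0.02
    frac_shared: float = 0.5
    slope_scale: float = 0.05      # log2 units per uM
    noise_sd: float = 0.3          # log2 units
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    # (size, driver_strength in log2 SD units, driver shape)
    module_specs: tuple[tuple[int, float, str], ...] = ((8, 1.5, "linear"),)
    # module-specific shared per-sample component mixed into the driver,
    # relative to the unit-SD dose trend: 0 makes the driver purely monotone
    # in dose, which is rank-identical to a strong responder and hence
    # undetectable as a distinct module under rank binning
    driver_jitter_sd: float = 1.0
    # the driver is redrawn until its standardized profile has at least this
    # gap at the tertile boundaries, so planted module membership is a
    # well-posed truth rather than an artifact of one noise realization
    driver_min_gap: float = 0.4
    absent_prob_low_expr: float = 0.3
    duplicate_symbol_frac: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_pos_block1": self.frac_pos_block1,
            "frac_neg_block1": self.frac_neg_block1,
            "frac_pos_block2": self.frac_pos_block2,
            "frac_neg_block2": self.frac_neg_block2,
            "frac_shared": self.frac_shared,
            "absent_prob_low_expr": self.absent_prob_low_expr,
            "duplicate_symbol_frac": self.duplicate_symbol_frac,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_pos_block1 + self.frac_neg_block1 > 1:
            raise ValueError("frac_pos_block1 + frac_neg_block1 exceeds 1")
        if self.frac_pos_block2 + self.frac_neg_block2 > 1:
            raise ValueError("frac_pos_block2 + frac_neg_block2 exceeds 1")
        for name, doses in (("doses_block1", self.doses_block1),
                            ("doses_block2", self.doses_block2)):
            d = list(doses)
            if len(d) < 3:
                raise ValueError(f"{name} has {len(d)} doses; regression needs >= 3")
            if d[0] != 0:
                raise ValueError(f"{name} must start at dose 0 (control)")
            if any(b <= a for a, b in zip(d, d[1:])):
                raise ValueError(f"{name} must be strictly increasing: {d}")
            if any(x < 0 for x in d):
                raise ValueError(f"{name} has a negative dose")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for size, strength, shape in self.module_specs:
            if size > self.n_genes:
                raise ValueError(f"module size {size} exceeds n_genes {self.n_genes}")
            if size < 2:
                raise ValueError(f"module size {size} too small")
            if shape not in DRIVER_SHAPES:
                raise ValueError(f"driver shape must be one of {DRIVER_SHAPES}, got {shape!r}")
        if self.noise_sd < 0 or self.slope_scale < 0:
            raise ValueError("noise_sd and slope_scale must be >= 0")
        if self.driver_jitter_sd < 0:
            raise ValueError("driver_jitter_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "module_specs" in raw:
            raw["module_specs"] = tuple(tuple(m) for m in raw["module_specs"])
        for key in ("doses_block1", "doses_block2"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["module_specs"] = [list(m) for m in self.module_specs]
        raw["doses_block1"] = list(self.doses_block1)
        raw["doses_block2"] = list(self.doses_block2)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SimulatedStudy:
    """An expression study plus the per-gene ground truth that produced it."""

    expression: ExpressionStudy
    truth: pd.DataFrame
    annotation: pd.DataFrame
    config: SimulationConfig


def _driver_profile(
    doses: np.ndarray,
    shape: str,
    jitter_sd: float,
    min_gap: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One module's shared latent profile over all samples, unit SD (ddof=0).

    A dose trend (monotone ``shape``) standardized to unit SD, mixed with a
    module-specific shared per-sample component of SD ``jitter_sd``; the mix
    is re-standardized so ``driver_strength`` always scales a unit-SD
    profile.
    """
    uniq = np.unique(doses)
    if shape == "linear":
        level = uniq / uniq.max()
    elif shape == "saturating":
        half = np.median(uniq[uniq > 0])
        level = uniq / (uniq + half)
    else:  # random_monotone: random positive increments between dose levels
        inc = rng.uniform(0.2, 1.0, size=len(uniq) - 1)
        level = np.concatenate([[0.0], np.cumsum(inc)])
    base = level[np.searchsorted(uniq, doses)]
    base = base - base.mean()
    sd = base.std()
    base = base / sd if sd > 0 else base
    if jitter_sd <= 0:
        return base
    # redraw the module-specific component until the standardized profile is
    # well spread at its tertile boundaries: membership of a planted module
    # should be decidable against the noise level, not a coin flip riding on
    # a near-tie in one latent realization
    n = len(doses)
    cuts = [c for c in np.linspace(0, n, 4).round().astype(int)[1:-1] if 0 < c < n]
    f = base
    for _ in range(200):
        f = base + rng.normal(0.0, jitter_sd, size=base.shape)
        f = f - f.mean()
        f = f / f.std()
        srt = np.sort(f)
        if all(srt[c] - srt[c - 1] >= min_gap for c in cuts):
            break
    return f


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one study (signals, calls, design, annotation) plus its truth table.

    Deterministic for a fixed config+seed.  Responder classes are assigned so
    that ``frac_shared`` of the smaller per-sign responder count is common to
    both blocks with consistent sign; module members are drawn from the
    remaining (non-responder) genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    d1 = np.asarray(config.doses_block1, dtype=float)
    d2 = np.asarray(config.doses_block2, dtype=float)
    doses = np.concatenate([d1, d2])
    blocks = np.concatenate([np.zeros(len(d1), int), np.ones(len(d2), int)])

    n_pos1 = round(config.frac_pos_block1 * n)
    n_neg1 = round(config.frac_neg_block1 * n)
    n_pos2 = round(config.frac_pos_block2 * n)
    n_neg2 = round(config.frac_neg_block2 * n)
    n_shared_pos = round(config.frac_shared * min(n_pos1, n_pos2))
    n_shared_neg = round(config.frac_shared * min(n_neg1, n_neg2))

    pool = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        if cursor + k > n:
            raise ValueError("responder/module fractions exceed the gene count")
        out = pool[cursor:cursor + k]
        cursor += k
        return out

    shared_pos = take(n_shared_pos)
    shared_neg = take(n_shared_neg)
    pos1_only = take(n_pos1 - n_shared_pos)
    neg1_only = take(n_neg1 - n_shared_neg)
    pos2_only = take(n_pos2 - n_shared_pos)
    neg2_only = take(n_neg2 - n_shared_neg)

    class1 = np.full(n, "null", dtype=object)
    class2 = np.full(n, "null", dtype=object)
    class1[np.concatenate([shared_pos, pos1_only]).astype(int)] = "positive"
    class1[np.concatenate([shared_neg, neg1_only]).astype(int)] = "negative"
    class2[np.concatenate([shared_pos, pos2_only]).astype(int)] = "positive"
    class2[np.concatenate([shared_neg, neg2_only]).astype(int)] = "negative"
    shared = np.zeros(n, dtype=bool)
    shared[np.concatenate([shared_pos, shared_neg]).astype(int)] = True

    module_id = np.full(n, -1, dtype=int)
    module_members: list[np.ndarray] = []
    for mid, (size, _strength, _shape) in enumerate(config.module_specs):
        members = take(size)
        module_id[members] = mid
        module_members.append(members)

    sign1 = np.where(class1 == "positive", 1.0, np.where(class1 == "negative", -1.0, 0.0))
    sign2 = np.where(class2 == "positive", 1.0, np.where(class2 == "negative", -1.0, 0.0))
    mag1 = config.slope_scale * rng.uniform(0.5, 1.5, size=n)
    mag2 = config.slope_scale * rng.uniform(0.5, 1.5, size=n)
    slope1 = sign1 * mag1
    slope2 = sign2 * mag2

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    dose_row = np.where(blocks == 0, 1.0, 0.0) * doses
    dose_row2 = np.where(blocks == 1, 1.0, 0.0) * doses
    log2sig = (
        baseline[:, None]
        + slope1[:, None] * dose_row[None, :]
        + slope2[:, None] * dose_row2[None, :]
    )
    for mid, (size, strength, shape) in enumerate(config.module_specs):
        members = module_members[mid]
        driver = _driver_profile(
            doses, shape, config.driver_jitter_sd, config.driver_min_gap, rng
        )
        loading = rng.uniform(0.8, 1.2, size=size)
        log2sig[members] += strength * loading[:, None] * driver[None, :]
    if config.noise_sd > 0:
        log2sig = log2sig + rng.normal(0.0, config.noise_sd, size=log2sig.shape)
    signal = 2.0 ** log2sig

    # detection calls from the baseline quartile
    calls = np.full(signal.shape, "P", dtype=object)
    low = baseline <= np.quantile(baseline, 0.25)
    absent = rng.random(signal.shape) < config.absent_prob_low_expr
    calls[low[:, None] & absent] = "A"

    probes = [f"P{i + 1:06d}" for i in range(n)]
    # many-probes-to-one-gene: a fraction of probes share the previous
    # probe's symbol, exercising probe collapsing downstream
    symbol_idx = np.arange(n)
    dup = np.flatnonzero(rng.random(n) < config.duplicate_symbol_frac)
    dup = dup[dup > 0]
    for i in dup:
        symbol_idx[i] = symbol_idx[i - 1]
    symbols = [f"G{symbol_idx[i] + 1:06d}" for i in range(n)]

    sample_ids = [
        f"d{int(t) if float(t).is_integer() else t}_{d:g}uM"
        for t, d in zip(
            np.where(blocks == 0, config.time_block1, config.time_block2), doses
        )
    ]
    design = pd.DataFrame(
        {
            "time_days": np.where(blocks == 0, config.time_block1, config.time_block2),
            "dose_uM": doses,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expression = ExpressionStudy(
        signal=pd.DataFrame(signal, index=pd.Index(probes, name="probe"), columns=sample_ids),
        calls=pd.DataFrame(calls, index=pd.Index(probes, name="probe"), columns=sample_ids),
        design=design,
    )
    annotation = pd.DataFrame(
        {
            "symbol": symbols,
            "gene_name": [f"synthetic gene {s}" for s in symbols],
        },
        index=pd.Index(probes, name="probe"),
    )
    truth = pd.DataFrame(
        {
            "symbol": symbols,
            "class_block1": class1,
            "class_block2": class2,
            "shared": shared,
            "module_id": module_id,
            "true_slope_block1": np.where(sign1 != 0, slope1, 0.0),
            "true_slope_block2": np.where(sign2 != 0, slope2, 0.0),
        },
        index=pd.Index(probes, name="probe"),
    )
    return SimulatedStudy(expression=expression, truth=truth,
                          annotation=annotation, config=config)


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write the full file set: expression/calls TSV, design CSV, annotation
    TSV, truth TSV and the config YAML; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression.tsv",
        "calls": outdir / "calls.tsv",
        "design": outdir / "design.csv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_expression(study.expression, paths["matrix"], paths["calls"], paths["design"])
    write_annotation(study.annotation, paths["annotation"])
    study.truth.rename_axis("probe").to_csv(paths["truth"], sep="\t")
    study.config.to_yaml(paths["config"])
    return paths
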