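"""Deterministic generators with planted activation/inhibition structure.

These generators are the test and validation substrate for the whole
package: they emit signal profiles, gene-by-sample cohorts and
differential-expression tables in exactly the shapes the readers and
scoring engine consume, together with a *truth record* naming the
planted structure, so downstream sensitivity/specificity can be
computed without re-deriving ground truth.

The noise model is Gaussian, with effects expressed in within-gene
standard-deviation units so power statements are dimensionless; a
heavy-tailed Student-t (df=3) switch exercises the rank/ECDF methods'
robustness.  Four single-profile scenarios mirror the canonical
pathway-diagram cases:

``activation``   activated genes shift up, inhibited genes shift down;
``inhibition``   the mirror image;
``mixed``        *both* lists shift up together - the trap case where a
                 membership-only enrichment test fires but a
                 bidirectional comparison correctly stays silent;
``null``         no shift anywhere.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from bdfunc.signatures import BidirectionalSignature

__all__ = [
    "PlantSpec",
    "SCENARIOS",
    "simulate_profile",
    "simulate_cohort",
    "simulate_differential_tables",
]

SCENARIOS = ("activation", "inhibition", "mixed", "null")
Scenario = Literal["activation", "inhibition", "mixed", "null"]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of a planted-signal simulation.

    ``effect`` is the mean shift of planted genes in units of the
    within-gene noise SD; ``baseline_sd`` is the spread of per-gene
    baselines shared across samples in cohorts (making columns look
    like real expression profiles rather than pure noise).
    """

    n_activated: int = 50
    n_inhibited: int = 50
    n_background: int = 900
    effect: float = 2.0
    noise_sd: float = 1.0
    baseline_sd: float = 1.0
    n_pos: int = 10
    n_neg: int = 10
    noise: Literal["normal", "t3"] = "normal"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_activated, self.n_inhibited, self.n_background) < 0:
            raise ValueError("gene counts must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _rngs(spec: PlantSpec, purpose: str, n: int) -> list[np.random.Generator]:
    """Independent child streams for one generator component.

    The purpose tag is folded in via a stable CRC32 so streams are
    reproducible across processes (unlike builtin ``hash``).
    """
    tag = zlib.crc32(purpose.encode())
    root = np.random.SeedSequence(entropy=spec.seed, spawn_key=(tag,))
    return [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(n)]


def _noise(rng: np.random.Generator, size, spec: PlantSpec) -> np.ndarray:
    if spec.noise == "t3":
        # standardized t(3): variance df/(df-2) = 3, rescale to noise_sd
        return rng.standard_t(3, size=size) / np.sqrt(3.0) * spec.noise_sd
    return rng.normal(0.0, spec.noise_sd, size=size)


def _gene_names(spec: PlantSpec) -> tuple[list[str], list[str], list[str]]:
    act = [f"ACT{i:04d}" for i in range(spec.n_activated)]
    inh = [f"INH{i:04d}" for i in range(spec.n_inhibited)]
    bg = [f"BG{i:05d}" for i in range(spec.n_background)]
    return act, inh, bg


def _signature(spec: PlantSpec, name: str = "PLANTED") -> BidirectionalSignature:
    act, inh, _ = _gene_names(spec)
    return BidirectionalSignature.from_gene_lists(name, act, inh)


def simulate_profile(
    spec: PlantSpec,
    scenario: Scenario = "activation",
) -> tuple[pd.Series, BidirectionalSignature, dict]:
    """One signal profile (e.g. a fold-change column) with planted structure.

    Returns ``(profile, signature, truth)``; the truth record carries
    the scenario, the shift applied to each list, and the expected sign
    of the activation statistic (+1, -1, or 0).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    act, inh, bg = _gene_names(spec)
    (rng,) = _rngs(spec, f"profile:{scenario}", 1)
    shift_act, shift_inh = {
        "activation": (+spec.effect, -spec.effect),
        "inhibition": (-spec.effect, +spec.effect),
        "mixed": (+spec.effect, +spec.effect),
        "null": (0.0, 0.0),
    }[scenario]
    values = np.concatenate([
        shift_act + _noise(rng, len(act), spec),
        shift_inh + _noise(rng, len(inh), spec),
        _noise(rng, len(bg), spec),
    ])
    profile = pd.Series(values, index=act + inh + bg, name=f"sim_{scenario}")
    truth = {
        "scenario": scenario,
        "shift_activated": shift_act,
        "shift_inhibited": shift_inh,
        "expected_sign": int(np.sign(shift_act - shift_inh)),
    }
    return profile, _signature(spec), truth


def simulate_cohort(
    spec: PlantSpec,
) -> tuple[pd.DataFrame, pd.Series, BidirectionalSignature, dict]:
    """A gene-by-sample cohort with positive/negative groups.

    Per-gene baselines are shared across all samples (columns look like
    correlated expression profiles); positive samples additionally carry
    the activation pattern (activated genes +effect, inhibited genes
    -effect, in noise-SD units), negative samples are null.
    """
    if spec.n_pos < 2 or spec.n_neg < 2:
        raise ValueError("need at least 2 samples per group")
    act, inh, bg = _gene_names(spec)
    genes = act + inh + bg
    rng_base, rng_noise = _rngs(spec, "cohort", 2)
    n_genes = len(genes)
    n_samples = spec.n_pos + spec.n_neg
    baseline = rng_base.normal(0.0, spec.baseline_sd, size=n_genes)
    mat = baseline[:, None] + _noise(rng_noise, (n_genes, n_samples), spec)
    direction = np.concatenate([
        np.full(len(act), +1.0), np.full(len(inh), -1.0), np.zeros(len(bg)),
    ])
    mat[:, : spec.n_pos] += spec.effect * spec.noise_sd * direction[:, None]
    samples = [f"POS{i:02d}" for i in range(spec.n_pos)] + [
        f"NEG{i:02d}" for i in range(spec.n_neg)
    ]
    table = pd.DataFrame(mat, index=genes, columns=samples)
    groups = pd.Series(
        ["positive"] * spec.n_pos + ["negative"] * spec.n_neg, index=samples
    )
    truth = {
        "effect": spec.effect,
        "positive_samples": samples[: spec.n_pos],
        "negative_samples": samples[spec.n_pos:],
        "activated_genes": act,
        "inhibited_genes": inh,
    }
    return table, groups, _signature(spec), truth


def simulate_differential_tables(
    n_tables: int,
    spec: PlantSpec,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> tuple[list[pd.DataFrame], dict]:
    """Differential tables with planted consensus structure.

    Planted "true" genes exceed the fold-change threshold with small
    p-values, consistently in every table; decoys include
    direction-flipped genes (sign reversed in the last table),
    sub-threshold fold-changes, and genes that lose significance in one
    table.  The truth record lists exactly which genes must survive the
    all-tables consistent-direction consensus rule.
    """
    if n_tables < 1:
        raise ValueError("n_tables must be >= 1")
    act, inh, bg = _gene_names(spec)
    rngs = _rngs(spec, "difftables", n_tables)
    n_decoy = max(len(bg) // 3, 1)
    flip = bg[:n_decoy]                       # direction flips in last table
    weak_fc = bg[n_decoy: 2 * n_decoy]        # |FC| below threshold everywhere
    weak_p = bg[2 * n_decoy: 3 * n_decoy]     # p above threshold in last table
    tables = []
    for t, rng in enumerate(rngs):
        recs = []
        strong_p = lambda n: rng.uniform(1e-8, p_threshold * 0.5, n)
        weak_pv = lambda n: rng.uniform(min(p_threshold * 2, 0.5), 0.9, n)
        strong_fc = lambda n: rng.uniform(fc_threshold * 1.2, fc_threshold * 3, n)
        small_fc = lambda n: rng.uniform(1.01, fc_threshold * 0.95, n)
        last = t == n_tables - 1
        for genes, fcs, ps in (
            (act, strong_fc(len(act)), strong_p(len(act))),
            (inh, -strong_fc(len(inh)), strong_p(len(inh))),
            (flip, (-1 if last else 1) * strong_fc(len(flip)), strong_p(len(flip))),
            (weak_fc, small_fc(len(weak_fc)), strong_p(len(weak_fc))),
            (weak_p, strong_fc(len(weak_p)),
             weak_pv(len(weak_p)) if last else strong_p(len(weak_p))),
        ):
            for g, fc, p in zip(genes, np.atleast_1d(fcs), np.atleast_1d(ps)):
                recs.append({"gene": g, "fold_change": float(fc),
                             "p_value": float(p), "fdr": float(min(p * 3, 1.0))})
        df = pd.DataFrame(recs).sample(frac=1.0, random_state=int(rng.integers(2**31)))
        tables.append(df.reset_index(drop=True))
    truth = {
        "consensus_activated": act if n_tables > 0 else [],
        "consensus_inhibited": inh,
        "decoys_flipped": flip,
        "decoys_weak_fc": weak_fc,
        "decoys_weak_p": weak_p,
    }
    return tables, truth
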