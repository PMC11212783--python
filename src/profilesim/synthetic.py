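"""Seeded synthetic dyadic emotion-rating data.

The generator emulates the *structure* of five study designs — an
experience-sampling study of couples (ESM), a video-mediated-recall lab task
(VMR), a single-occasion lab questionnaire, and two cross-cultural surveys —
not their substantive findings.  The generative model is deliberately the
simplest one with a single interpretable dyad-similarity knob:

* a shared dyadic affect state ``s_gt ~ N(0,1)`` per couple-occasion, mixed
  into each member's latent state ``u = sqrt(rho)*s + sqrt(1-rho)*e`` so that
  ``rho`` (``dyad_similarity``) is the latent within-couple correlation;
* valence-driven normative similarity: positive-valence variables sit
  ``normative_effect`` scale units above negative-valence ones for everybody,
  the stereotype pattern that centering is meant to remove;
* person-level trait offsets, occasion noise, clipping to the rating scale
  and optional rounding (Likert-type designs);
* zero inflation: negative-valence ratings floor to the scale minimum with a
  given probability, driving 0/0 degeneracies in measures such as the
  Canberra distance;
* whole-occasion joint missingness: both members answer with probability
  ``joint_response_rate``, otherwise a random single member answers;
* a small fraction of careless responders who straight-line (per-person
  constant plus tiny jitter).

Cultural designs replace the shared couple state with culture-level mean
offsets; the "dyad" is individual-versus-norm and is formed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .preprocessing import CenteringSpec, LongDataset

__all__ = ["GeneratorConfig", "generate", "design_config", "default_suite",
           "SUITE_DESIGNS"]

SUITE_DESIGNS = ("esm", "vmr", "lab", "cult14", "cult20")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generative model; see the module docstring.

    Scale-unit parameters (``normative_effect``, ``noise_sd``, ...) are in
    the units of ``scale``.  ``latent_loading`` converts one SD of latent
    affect into scale units; ``trait_sd`` / ``culture_sd`` size person and
    culture offsets.  When left ``None`` they default to 12% / 8% / 8% of
    the scale width.
    """

    design: str
    n_groups: int
    p_variables: int
    valence: tuple[int, ...]
    scale: tuple[float, float]
    members_per_group: int = 2
    n_occasions: int = 1
    rounded: bool = True
    normative_effect: float = 0.0
    dyad_similarity: float = 0.4
    zero_inflation: float = 0.0
    joint_response_rate: float = 1.0
    careless_fraction: float = 0.01
    noise_sd: float = 1.0
    latent_loading: Optional[float] = None
    trait_sd: Optional[float] = None
    culture_sd: Optional[float] = None
    variables: Optional[tuple[str, ...]] = None
    dataset_id: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.scale
        if not lo < hi:
            raise ValueError("scale must satisfy lo < hi")
        if self.p_variables < 2:
            raise ValueError("need at least 2 variables")
        if len(self.valence) != self.p_variables:
            raise ValueError("valence must have one entry per variable")
        if any(v not in (-1, 1) for v in self.valence):
            raise ValueError("valence entries must be +1 or -1")
        for name in ("zero_inflation", "careless_fraction", "dyad_similarity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.joint_response_rate <= 1.0:
            raise ValueError("joint_response_rate must lie in (0, 1]")
        if self.n_groups < 1 or self.n_occasions < 1:
            raise ValueError("need at least one group and occasion")

    @property
    def width(self) -> float:
        return self.scale[1] - self.scale[0]

    def _loading(self) -> float:
        return self.latent_loading if self.latent_loading is not None \
            else 0.12 * self.width

    def _trait_sd(self) -> float:
        return self.trait_sd if self.trait_sd is not None else 0.08 * self.width

    def _culture_sd(self) -> float:
        return self.culture_sd if self.culture_sd is not None \
            else 0.08 * self.width

    def variable_names(self) -> list[str]:
        if self.variables is not None:
            return list(self.variables)
        return [f"v{j + 1}" for j in range(self.p_variables)]


def _generate_dyadic(cfg: GeneratorConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    G, T, p = cfg.n_groups, cfg.n_occasions, cfg.p_variables
    lo, hi = cfg.scale
    val = np.asarray(cfg.valence, dtype=float)
    base = (lo + hi) / 2.0
    rho = cfg.dyad_similarity

    s = rng.standard_normal((G, T))
    e = rng.standard_normal((G, T, 2))
    u = np.sqrt(rho) * s[..., None] + np.sqrt(1.0 - rho) * e
    traits = rng.normal(0.0, cfg._trait_sd(), size=(G, 2, p))
    noise = rng.normal(0.0, cfg.noise_sd, size=(G, T, 2, p))

    values = (base + val * cfg.normative_effect / 2.0
              + cfg._loading() * val * u[..., None]
              + traits[:, None, :, :] + noise)

    if cfg.zero_inflation > 0:
        floor = rng.random((G, T, 2, p)) < cfg.zero_inflation
        floor &= val < 0
        values = np.where(floor, lo, values)

    careless = rng.random((G, 2)) < cfg.careless_fraction
    # broadcast careless (G,2) over occasions: reshape to (G,1,2)
    const = rng.uniform(lo, hi, size=(G, 2))
    jitter = rng.normal(0.0, 0.02 * cfg.width, size=values.shape)
    values = np.where(careless[:, None, :, None],
                      const[:, None, :, None] + jitter, values)
    values = np.clip(values, lo, hi)
    if cfg.rounded:
        values = np.round(values)

    # joint-occasion missingness: both answer w.p. joint_response_rate,
    # otherwise exactly one randomly chosen member answers
    joint = rng.random((G, T)) < cfg.joint_response_rate
    solo = rng.integers(0, 2, size=(G, T))
    present = np.ones((G, T, 2), dtype=bool)
    present[~joint] = False
    gi, ti = np.nonzero(~joint)
    present[gi, ti, solo[gi, ti]] = True

    rows = []
    roles = ("A", "B")
    names = cfg.variable_names()
    for g in range(G):
        gid = f"g{g + 1:03d}"
        for m in range(2):
            pid = f"{gid}{roles[m]}"
            for t in range(T):
                if present[g, t, m]:
                    rows.append((gid, pid, roles[m], t + 1,
                                 *values[g, t, m, :]))
    return pd.DataFrame(rows, columns=["group_id", "person_id", "role",
                                       "occasion_id", *names])


def _generate_culture(cfg: GeneratorConfig, rng: np.random.Generator
                      ) -> pd.DataFrame:
    G, M, p = cfg.n_groups, cfg.members_per_group, cfg.p_variables
    lo, hi = cfg.scale
    val = np.asarray(cfg.valence, dtype=float)
    base = (lo + hi) / 2.0

    offsets = rng.normal(0.0, cfg._culture_sd(), size=(G, p))
    u = rng.standard_normal((G, M))
    noise = rng.normal(0.0, cfg.noise_sd, size=(G, M, p))
    values = (base + val * cfg.normative_effect / 2.0 + offsets[:, None, :]
              + cfg._loading() * val * u[..., None] + noise)

    if cfg.zero_inflation > 0:
        floor = rng.random((G, M, p)) < cfg.zero_inflation
        floor &= val < 0
        values = np.where(floor, lo, values)

    careless = rng.random((G, M)) < cfg.careless_fraction
    const = rng.uniform(lo, hi, size=(G, M))
    jitter = rng.normal(0.0, 0.02 * cfg.width, size=values.shape)
    values = np.where(careless[..., None], const[..., None] + jitter, values)
    values = np.clip(values, lo, hi)
    if cfg.rounded:
        values = np.round(values)

    rows = []
    names = cfg.variable_names()
    for g in range(G):
        gid = f"c{g + 1:02d}"
        for m in range(M):
            rows.append((gid, f"{gid}m{m + 1:03d}", "member", 1,
                         *values[g, m, :]))
    return pd.DataFrame(rows, columns=["group_id", "person_id", "role",
                                       "occasion_id", *names])


def generate(cfg: GeneratorConfig) -> LongDataset:
    """Generate one seeded dataset; same config (incl. seed) => same bytes."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.design == "culture_like":
        frame = _generate_culture(cfg, rng)
        default = CenteringSpec("grand_mean")
    else:
        frame = _generate_dyadic(cfg, rng)
        default = CenteringSpec("person_mean") if cfg.n_occasions > 1 \
            else CenteringSpec("variable_mean_by_role")
    ds = LongDataset(
        dataset_id=cfg.dataset_id or cfg.design,
        design=cfg.design,
        frame=frame,
        variables=cfg.variable_names(),
        scale=cfg.scale,
        default_centering=default,
    )
    ds.validate()
    return ds


# emotion labels of the five emulated designs
_ESM_VARS = ("angry", "sad", "anxious", "relaxed", "happy", "lonely")
_ESM_VALENCE = (-1, -1, -1, 1, 1, -1)
_VMR_VARS = ("annoyed", "resigned", "hurt", "afraid_hurting", "guilty",
             "aloof", "worried", "embarrassed", "empathy", "strong",
             "calm", "amae")
_VMR_VALENCE = (-1, -1, -1, -1, -1, -1, -1, -1, 1, 1, 1, 1)
_LAB_VARS = ("angry", "sad", "anxious", "relaxed", "happy", "stress")
_LAB_VALENCE = (-1, -1, -1, 1, 1, -1)
_CULT14_VARS = ("pleasant", "unpleasant", "happy", "cheerful", "sad", "angry",
                "proud", "grateful", "love", "guilty", "ashamed", "worried",
                "stressed", "jealous")
_CULT14_VALENCE = (1, -1, 1, 1, -1, -1, 1, 1, 1, -1, -1, -1, -1, -1)
_CULT20_VARS = ("upset", "irritated", "guilty", "ashamed", "afraid",
                "interested", "strong", "proud", "bored", "jealous",
                "ill_feelings", "close", "respect", "in_debt", "relying",
                "resigned", "helpful", "surprised", "worthless", "embarrassed")
_CULT20_VALENCE = (-1, -1, -1, -1, -1, 1, 1, 1, -1, -1, -1, 1, 1, -1, 1,
                   -1, 1, 1, -1, -1)


def design_config(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Default configuration for one of the five emulated designs.

    Structural parameters (group counts, variable counts, scales,
    longitudinal vs cross-sectional, the 88% ESM joint-response rate) follow
    the emulated studies; cultural designs are scaled to 30 members per
    culture, which exercises the method at desk scale.
    """
    presets = {
        "esm": dict(design="esm_like", n_groups=94, n_occasions=70,
                    p_variables=6, valence=_ESM_VALENCE, variables=_ESM_VARS,
                    scale=(0.0, 100.0), rounded=False, normative_effect=50.0,
                    zero_inflation=0.25, joint_response_rate=0.88,
                    noise_sd=10.0, dataset_id="esm"),
        "vmr": dict(design="vmr_like", n_groups=133, n_occasions=20,
                    p_variables=12, valence=_VMR_VALENCE, variables=_VMR_VARS,
                    scale=(0.0, 6.0), rounded=True, normative_effect=3.0,
                    zero_inflation=0.35, joint_response_rate=0.95,
                    noise_sd=0.6, dataset_id="vmr"),
        "lab": dict(design="lab_like", n_groups=101, n_occasions=1,
                    p_variables=6, valence=_LAB_VALENCE, variables=_LAB_VARS,
                    scale=(1.0, 7.0), rounded=True, normative_effect=3.0,
                    zero_inflation=0.05, joint_response_rate=1.0,
                    noise_sd=0.6, dataset_id="lab"),
        "cult14": dict(design="culture_like", n_groups=48,
                       members_per_group=30, p_variables=14,
                       valence=_CULT14_VALENCE, variables=_CULT14_VARS,
                       scale=(1.0, 9.0), rounded=True, normative_effect=4.0,
                       zero_inflation=0.0, dyad_similarity=0.0,
                       noise_sd=0.8, dataset_id="cult14"),
        "cult20": dict(design="culture_like", n_groups=12,
                       members_per_group=30, p_variables=20,
                       valence=_CULT20_VALENCE, variables=_CULT20_VARS,
                       scale=(1.0, 7.0), rounded=True, normative_effect=3.0,
                       zero_inflation=0.0, dyad_similarity=0.0,
                       noise_sd=0.6, dataset_id="cult20"),
    }
    if name not in presets:
        raise ValueError(f"unknown design preset {name!r}; "
                         f"choose from {sorted(presets)}")
    kw = presets[name]
    kw.update(overrides)
    return GeneratorConfig(seed=seed, **kw)


def default_suite(seed: int = 0, **overrides) -> list[LongDataset]:
    """The five default datasets, with design-matched centering attached.

    Per-dataset seeds are spawned from ``seed`` so the suite is reproducible
    from a single integer.
    """
    children = np.random.SeedSequence(seed).spawn(len(SUITE_DESIGNS))
    out = []
    for name, child in zip(SUITE_DESIGNS, children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(generate(design_config(name, seed=sub_seed, **overrides)))
    return out
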