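"""Synthetic rarefied-style OTU tables with known ground truth.

Latent factor model: each module has a per-sample Gaussian factor; a member
taxon's latent log-abundance is a signed loading on its module factor plus
independent noise, scaled to unit variance.  Negative associations come from
negative loadings.  Hub taxa get elevated loadings; connector taxa load on
several modules at once.  Counts are multinomial draws at a fixed depth from
the softmax of baseline + latent, emulating a rarefied count table.

A multi-stage schedule raises coupling, module count and the negative
fraction stage by stage, so network size, connectivity, negative-link ratio
and N:P are all expected to increase with stage while positive cohesion
decreases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = [
    "StageSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_stage",
    "generate_series",
    "strong_module_spec",
    "role_recovery_spec",
    "independent_spec",
    "default_series_spec",
]


@dataclass
class StageSpec:
    """Parameters for one developmental stage's community."""

    label: str
    n_samples: int
    module_sizes: list
    coupling: tuple = (0.9, 0.9)  # target within-module pair |r| range
    negative_fraction: float = 0.2  # target fraction of negative within-module pairs
    n_background: int = 0
    n_rare: int = 0
    n_hubs: int = 0  # hub taxa per module (counted inside module_sizes)
    hub_coupling: float = 0.97
    n_connectors: int = 0
    connector_coupling: float = 0.9
    connector_n_modules: int = 3
    depth: int = 14_666
    baseline_log_sd: float = 0.75
    rare_target_abundance: float = 3e-5
    latent_sd: float = 1.0
    # module taxa get latent_sd * module_latent_scale: < 1 damps the
    # factor-driven compositional push on unrelated taxa while leaving
    # within-module rank correlations untouched
    module_latent_scale: float = 1.0
    dph: list = field(default_factory=lambda: [30])

    @property
    def n_taxa(self) -> int:
        return sum(self.module_sizes) + self.n_connectors + self.n_background + self.n_rare

    def validate(self) -> None:
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if not (0 <= self.negative_fraction <= 1):
            raise ValueError("negative_fraction must be in [0, 1]")
        if self.negative_fraction > 0.5:
            raise ValueError(
                "negative_fraction > 0.5 is infeasible with sign-of-loading "
                "couplings (max attainable negative pair fraction is 0.5)"
            )
        if any(s < self.n_hubs for s in self.module_sizes):
            raise ValueError("module smaller than its hub count")
        if self.n_connectors and len(self.module_sizes) < self.connector_n_modules:
            raise ValueError("not enough modules for connector placement")
        lo, hi = self.coupling
        if not (0 < lo <= hi < 1):
            raise ValueError("coupling range must lie in (0, 1)")


@dataclass
class SyntheticSpec:
    """A schedule of stages plus the global seed."""

    stages: list
    seed: int = 0

    def validate(self) -> None:
        for s in self.stages:
            s.validate()


@dataclass
class GroundTruth:
    """Planted structure serialized alongside every generated table."""

    stage_label: str
    module_of: dict  # taxon -> module index (module members only)
    role_of: dict  # taxon -> hub | connector | member | background | rare
    sign_of: dict  # taxon -> +1/-1 loading sign (module members only)
    connector_modules: dict  # connector taxon -> list of module indices
    np_rank: int  # intended N:P rank of this stage within the series

    def pair_sign(self, a: str, b: str) -> int | None:
        """Intended correlation sign for a within-module pair (else None)."""
        if (
            a in self.module_of
            and b in self.module_of
            and self.module_of[a] == self.module_of[b]
        ):
            return self.sign_of[a] * self.sign_of[b]
        return None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        doc["module_of"] = {k: int(v) for k, v in doc["module_of"].items()}
        doc["sign_of"] = {k: int(v) for k, v in doc["sign_of"].items()}
        doc["connector_modules"] = {
            k: [int(x) for x in v] for k, v in doc["connector_modules"].items()
        }
        return cls(**doc)


def _negative_loading_prob(fraction: float) -> float:
    # fraction of negative within-module pairs is 2q(1-q) for loading-sign
    # probability q; invert on [0, 0.5]
    return (1.0 - np.sqrt(1.0 - 2.0 * fraction)) / 2.0


def generate_stage(
    spec: SyntheticSpec, stage: int, np_rank: int | None = None
) -> tuple[CountTable, GroundTruth]:
    """Generate one stage's count table and its ground truth.

    Deterministic given ``spec.seed`` and the stage index.
    """
    spec.validate()
    st = spec.stages[stage]
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, stage)))
    n_modules = len(st.module_sizes)
    q = _negative_loading_prob(st.negative_fraction)

    taxa: list[str] = []
    module_of: dict = {}
    role_of: dict = {}
    sign_of: dict = {}
    connector_modules: dict = {}

    # assemble taxon roster
    idx = 0
    members: list[tuple[str, int, bool]] = []  # (taxon, module, is_hub)
    for m, size in enumerate(st.module_sizes):
        for j in range(size):
            name = f"OTU{idx:04d}"
            idx += 1
            taxa.append(name)
            is_hub = j < st.n_hubs
            members.append((name, m, is_hub))
            module_of[name] = m
            role_of[name] = "hub" if is_hub else "member"
    connectors = []
    for j in range(st.n_connectors):
        name = f"OTU{idx:04d}"
        idx += 1
        taxa.append(name)
        mods = [(j + k) % n_modules for k in range(st.connector_n_modules)]
        connectors.append((name, mods))
        connector_modules[name] = mods
        role_of[name] = "connector"
    for j in range(st.n_background):
        name = f"OTU{idx:04d}"
        idx += 1
        taxa.append(name)
        role_of[name] = "background"
    rare = []
    for j in range(st.n_rare):
        name = f"OTU{idx:04d}"
        idx += 1
        taxa.append(name)
        rare.append(name)
        role_of[name] = "rare"
    n_taxa = len(taxa)

    # latent factors and loadings
    factors = rng.normal(size=(st.n_samples, n_modules))
    noise = rng.normal(size=(st.n_samples, n_taxa))
    z = np.empty((st.n_samples, n_taxa))
    lo, hi = st.coupling
    col = {t: i for i, t in enumerate(taxa)}
    for name, m, is_hub in members:
        target = st.hub_coupling if is_hub else rng.uniform(lo, hi)
        c = np.sqrt(target)  # pair corr between equals = c_i * c_j
        a = c / np.sqrt(1.0 - c**2)
        sign = 1 if (is_hub or rng.random() >= q) else -1
        sign_of[name] = sign
        i = col[name]
        raw = sign * a * factors[:, m] + noise[:, i]
        z[:, i] = (
            st.latent_sd * st.module_latent_scale * raw / np.sqrt(a**2 + 1.0)
        )
    for jc, (name, mods) in enumerate(connectors):
        c = np.sqrt(st.connector_coupling)
        a = c / np.sqrt(1.0 - c**2)
        i = col[name]
        # Hadamard-style sign rows keep distinct connectors uncorrelated
        signs = np.array(
            [(-1) ** bin((jc + 1) & k).count("1") for k in range(len(mods))]
        )
        combo = (factors[:, mods] * signs).sum(axis=1) / np.sqrt(len(mods))
        raw = a * combo + noise[:, i]
        z[:, i] = (
            st.latent_sd * st.module_latent_scale * raw / np.sqrt(a**2 + 1.0)
        )
    for name in taxa:
        if role_of[name] in ("background", "rare"):
            z[:, col[name]] = st.latent_sd * noise[:, col[name]]

    # baselines: lognormal spread; rare taxa pinned far below 0.01%
    baseline = rng.normal(0.0, st.baseline_log_sd, size=n_taxa)
    if rare:
        bulk = np.exp(
            baseline[[col[t] for t in taxa if role_of[t] != "rare"]]
        ).sum()
        for t in rare:
            baseline[col[t]] = np.log(st.rare_target_abundance * bulk)

    logits = baseline[None, :] + z
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((n_taxa, st.n_samples), dtype=np.int64)
    for s in range(st.n_samples):
        counts[:, s] = rng.multinomial(st.depth, probs[s])

    sample_ids = [f"{st.label}_s{k:03d}" for k in range(st.n_samples)]
    metadata = pd.DataFrame(
        {
            "dph": [st.dph[k % len(st.dph)] for k in range(st.n_samples)],
            "stage": st.label,
            "tank": [f"T{k % 3 + 1}" for k in range(st.n_samples)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = CountTable(
        pd.DataFrame(counts, index=taxa, columns=sample_ids), metadata=metadata
    )
    truth = GroundTruth(
        stage_label=st.label,
        module_of=module_of,
        role_of=role_of,
        sign_of=sign_of,
        connector_modules=connector_modules,
        np_rank=stage if np_rank is None else np_rank,
    )
    return table, truth


def generate_series(spec: SyntheticSpec) -> list[tuple[CountTable, GroundTruth]]:
    """Generate every stage of the schedule (N:P rank = stage order)."""
    if len(spec.stages) < 2:
        raise ValueError("need at least 2 stages for a series")
    return [generate_stage(spec, i, np_rank=i) for i in range(len(spec.stages))]


# ---------------------------------------------------------------------------
# Canned specifications
# ---------------------------------------------------------------------------

def strong_module_spec(seed: int = 0, n_samples: int = 100) -> SyntheticSpec:
    """Three well-separated 15-taxon modules; module recovery benchmark."""
    return SyntheticSpec(
        stages=[
            StageSpec(
                label="strong",
                n_samples=n_samples,
                module_sizes=[15, 15, 15],
                coupling=(0.96, 0.96),
                negative_fraction=0.3,
                n_background=60,
                baseline_log_sd=0.3,
                dph=[30],
            )
        ],
        seed=seed,
    )


def role_recovery_spec(seed: int = 0, n_samples: int = 220) -> SyntheticSpec:
    """Planted hubs and connectors; role recovery benchmark.

    Build the network at :data:`ROLE_RECOVERY_ST` -- member couplings
    straddle it so module interiors stay sparse enough for hubs to stand
    out, while connectors (which split their variance over the module
    factors and therefore cannot reach high |r| with any single module)
    still link into every module.  Loading signs are balanced so the
    compositional closure stays factor-neutral.
    """
    return SyntheticSpec(
        stages=[
            StageSpec(
                label="roles",
                n_samples=n_samples,
                module_sizes=[18, 18, 18, 18],
                coupling=(0.08, 0.35),
                negative_fraction=0.5,
                n_hubs=1,
                hub_coupling=0.97,
                n_connectors=4,
                connector_coupling=0.95,
                connector_n_modules=4,
                baseline_log_sd=0.4,
                dph=[30],
            )
        ],
        seed=seed,
    )


#: Similarity threshold recommended for role_recovery_spec networks.
ROLE_RECOVERY_ST = 0.28


def independent_spec(seed: int = 0, n_taxa: int = 50, n_samples: int = 100) -> SyntheticSpec:
    """Fully independent taxa; null calibration benchmark."""
    return SyntheticSpec(
        stages=[
            StageSpec(
                label="null",
                n_samples=n_samples,
                module_sizes=[],
                n_background=n_taxa,
                baseline_log_sd=0.3,
                latent_sd=0.6,
                dph=[30],
            )
        ],
        seed=seed,
    )


def default_series_spec(seed: int = 0, n_samples: int = 100) -> SyntheticSpec:
    """Three-stage schedule with increasing connectivity and competition.

    Later stages have more module taxa (so more nodes and links above the
    prevalence filter), stronger coupling (more edges at a fixed threshold)
    and a larger negative fraction, so the negative-link ratio and N:P rise
    with stage while positive cohesion falls.
    """
    common = dict(baseline_log_sd=0.5, n_rare=3, module_latent_scale=0.5)
    return SyntheticSpec(
        stages=[
            StageSpec(
                label="S1",
                n_samples=n_samples,
                module_sizes=[12, 12, 12],
                coupling=(0.80, 0.88),
                negative_fraction=0.02,
                n_background=40,
                dph=[12, 20],
                **common,
            ),
            StageSpec(
                label="S2",
                n_samples=n_samples,
                module_sizes=[12, 12, 12, 12],
                coupling=(0.87, 0.94),
                negative_fraction=0.30,
                n_background=60,
                dph=[27, 42],
                **common,
            ),
            StageSpec(
                label="S3",
                n_samples=n_samples,
                module_sizes=[13, 13, 13, 13, 13],
                coupling=(0.93, 0.97),
                negative_fraction=0.50,
                n_background=80,
                dph=[56, 70, 98],
                **common,
            ),
        ],
        seed=seed,
    )
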