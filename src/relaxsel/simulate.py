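"""Synthetic meta-analytic datasets with the structure the analysis assumes.

Each context gets species-level trajectories with phylogenetic signal:
the latent analysis-scale response of record i is

    resp_i = f(x_i) + u_species + u_phylo + u_study + u_trait_type + e_i

with ``f`` the inverse-decay mean trajectory, ``u_phylo`` drawn jointly
with covariance sigma2_phylo * A from a pure-birth tree, the other levels
spherical, and ``e_i ~ N(0, sigma_e^2 / n_i)`` (heteroscedastic, scaled
by the record's sample size).  Raw record means embed the latent response
through a per-(study, trait) affine map so the data-prep standardization
is exercised; raw SDs are set so each record's |CV| follows the Weibull
bump trajectory times multiplicative lognormal noise.

Default parameters encode the study conditions the analysis targets:
decay factors chosen so the mean trait reaches its asymptote (5%
criterion) after ~30 generations under domestication and ~90 under
urbanization, captivity intermediate; CV baselines equal across contexts
at generation 0, with a domestication bump peaking near generation 18 and
declining past 50.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .curves import InverseParams, WeibullParams, inverse_curve, weibull_curve
from .phylo import read_newick, phylo_correlation
from .prep import RECORD_COLUMNS, FORAGING_GUILDS, SOCIALITY

__all__ = [
    "ContextConfig",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_lifehistory",
    "simulate_dataset",
    "write_fixture_bundle",
    "default_config",
]


@dataclass
class ContextConfig:
    """Ground truth and sampling structure for one context."""

    mean_params: InverseParams
    cv_params: WeibullParams
    n_studies: int = 20
    traits_per_study: int = 2
    generations: tuple = (0.0, 2.0, 5.0, 10.0, 20.0, 35.0, 60.0, 100.0)
    sd: dict = field(
        default_factory=lambda: {
            "species": 0.3, "phylogeny": 0.3, "study": 0.4, "trait_type": 0.2,
        }
    )
    residual_sd: float = 0.3
    cv_noise_sd: float = 0.15
    sample_size_range: tuple = (5, 30)
    raw_offset: float = 5.0  # per-(study,trait) embedding: offset + scale*resp
    raw_scale: float = 1.0


@dataclass
class SimulationConfig:
    """Full generator configuration: contexts, tree and life-history model."""

    contexts: dict = field(default_factory=dict)
    n_species: int = 30
    birth_rate: float = 1.0
    guild_probs: dict = field(
        default_factory=lambda: {
            "carnivore": 0.15, "omnivore": 0.25, "herbivore": 0.25,
            "granivore": 0.2, "insectivore": 0.15,
        }
    )
    gregarious_prob: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=str)


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions (see module docstring)."""
    contexts = {
        # 0.05 ** (1/30) = 0.9050 -> asymptote (5% criterion) at 30 generations
        "domestication": ContextConfig(
            mean_params=InverseParams(y_ini=-0.5, k=1.5, a=0.9050),
            cv_params=WeibullParams(y_ini=0.5, a=8.0, k=2.0, lam=25.0, t_min=0.0),
        ),
        # 0.05 ** (1/90) = 0.9673 -> asymptote at 90 generations
        "urbanization": ContextConfig(
            mean_params=InverseParams(y_ini=-0.5, k=1.5, a=0.9673),
            cv_params=WeibullParams(y_ini=0.5, a=6.0, k=2.0, lam=60.0, t_min=0.0),
            generations=(0.0, 5.0, 15.0, 30.0, 60.0, 90.0, 130.0, 180.0),
        ),
        # intermediate speed, weak CV bump (the context with the weakest signal)
        "captivity": ContextConfig(
            mean_params=InverseParams(y_ini=-0.5, k=1.2, a=0.95),
            cv_params=WeibullParams(y_ini=0.5, a=2.0, k=2.0, lam=40.0, t_min=0.0),
            n_studies=12,
        ),
    }
    return SimulationConfig(contexts=contexts, seed=seed)


@dataclass
class SimulatedDataset:
    """Records + life history + tree + serialized ground truth."""

    records: pd.DataFrame
    lifehistory: pd.DataFrame
    newick: str
    truth: dict


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> str:
    """Pure-birth (Yule) ultrametric tree, height normalized to 1.

    Leaves are labelled ``sp_001 ... sp_N``.  Returns a newick string;
    deterministic given the seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    from dendropy.simulate import treesim

    rng = _random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=rng,
    )
    # normalize all leaf depths to exactly 1
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(l.root_distance for l in tree.leaf_node_iter())
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = e.length / height
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 1.0 - leaf.root_distance
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    ):
        leaf.taxon.label = f"sp_{i + 1:03d}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_lifehistory(species: list[str], config: SimulationConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    guilds = list(config.guild_probs)
    probs = np.array([config.guild_probs[g] for g in guilds], dtype=float)
    probs = probs / probs.sum()
    rows = []
    for sp in species:
        rows.append(
            {
                "species_id": sp,
                "foraging_guild": guilds[rng.choice(len(guilds), p=probs)],
                "sociality": "gregarious"
                if rng.random() < config.gregarious_prob
                else "solitary",
                "max_longevity": float(np.exp(rng.normal(np.log(10.0), 0.5))),
                "taxon": "Simulated",
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate a full dataset per the configured generative model.

    The returned records table carries the standard observation columns
    plus a ``latent_response`` ground-truth column (the analysis-scale
    response before the raw-scale embedding), so stages downstream of the
    data-prep standardization can also be tested in isolation.
    """
    if config is None:
        config = default_config(seed=seed if seed is not None else 0)
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    tree_seed = int(rng.integers(0, 2**31 - 1))
    newick = simulate_tree(config.n_species, config.birth_rate, seed=tree_seed)
    species = [f"sp_{i + 1:03d}" for i in range(config.n_species)]
    lh = simulate_lifehistory(species, config, rng)

    tree = read_newick(newick)
    A = phylo_correlation(tree).reorder(species).matrix
    L_A = np.linalg.cholesky(A + 1e-10 * np.eye(len(species)))

    trait_classes = ("behavioral", "physiological")
    frames = []
    truth: dict = {"seed": config.seed, "contexts": {}}
    for ctx, cc in config.contexts.items():
        if any(v < 0 for v in cc.sd.values()) or cc.residual_sd < 0:
            raise ValueError("random-effect and residual SDs must be non-negative")
        grid = np.asarray(cc.generations, dtype=float)
        if np.any(grid < 0):
            raise ValueError("generations must be non-negative")
        # per-context random effects
        u_species = rng.normal(0, cc.sd["species"], config.n_species)
        u_phylo = cc.sd["phylogeny"] * (L_A @ rng.standard_normal(config.n_species))
        u_study = rng.normal(0, cc.sd["study"], cc.n_studies)
        u_trait_type = rng.normal(0, cc.sd["trait_type"], len(trait_classes))
        study_species = rng.integers(0, config.n_species, cc.n_studies)

        rows = []
        for s in range(cc.n_studies):
            sp_idx = int(study_species[s])
            for t in range(cc.traits_per_study):
                tc_idx = int(rng.integers(0, len(trait_classes)))
                trait_id = f"{ctx[:3]}_s{s + 1:02d}_t{t + 1}"
                off = cc.raw_offset
                scale = cc.raw_scale
                for x in grid:
                    n_i = int(rng.integers(cc.sample_size_range[0],
                                           cc.sample_size_range[1] + 1))
                    e = rng.normal(0, cc.residual_sd / np.sqrt(n_i))
                    resp = (
                        float(inverse_curve(x, cc.mean_params))
                        + u_species[sp_idx] + u_phylo[sp_idx]
                        + u_study[s] + u_trait_type[tc_idx] + e
                    )
                    cv = float(weibull_curve(x, cc.cv_params))
                    if cv < 0:
                        raise ValueError(
                            f"CV trajectory negative at generation {x}; "
                            "inconsistent configuration"
                        )
                    cv_obs = cv * float(np.exp(rng.normal(0, cc.cv_noise_sd)))
                    raw_mean = off + scale * resp
                    rows.append(
                        {
                            "context": ctx,
                            "study_id": f"{ctx[:3]}_s{s + 1:02d}",
                            "species_id": species[sp_idx],
                            "trait_id": trait_id,
                            "trait_class": trait_classes[tc_idx],
                            "generation": float(x),
                            "raw_mean": raw_mean,
                            "raw_sd": abs(raw_mean) * cv_obs,
                            "sample_size": n_i,
                            "direction": 1,
                            "selected_for_high_fear": False,
                            "latent_response": resp,
                        }
                    )
        frames.append(pd.DataFrame(rows))
        truth["contexts"][ctx] = {
            "mean_params": cc.mean_params.to_dict(),
            "cv_params": cc.cv_params.to_dict(),
            "sd": dict(cc.sd),
            "residual_sd": cc.residual_sd,
            "cv_noise_sd": cc.cv_noise_sd,
            "n_studies": cc.n_studies,
            "traits_per_study": cc.traits_per_study,
            "generations": [float(g) for g in cc.generations],
        }
    records = pd.concat(frames, ignore_index=True)[
        RECORD_COLUMNS + ["latent_response"]
    ]
    return SimulatedDataset(records=records, lifehistory=lh, newick=newick, truth=truth)


def write_fixture_bundle(dataset: SimulatedDataset, directory) -> list[Path]:
    """Write records.csv, lifehistory.csv, tree.nwk and truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = [
        d / "records.csv",
        d / "lifehistory.csv",
        d / "tree.nwk",
        d / "truth.json",
    ]
    dataset.records.to_csv(paths[0], index=False)
    dataset.lifehistory.to_csv(paths[1], index=False)
    paths[2].write_text(dataset.newick + "\n")
    paths[3].write_text(json.dumps(dataset.truth, indent=2))
    return paths
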