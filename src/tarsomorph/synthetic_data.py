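"""Synthetic landmark datasets with the statistical structure the analysis
assumes, for testing and for calibrating the decision rule.

Each landmark coordinate evolves independently down the tree as Brownian
motion (variance ``sigma**2 * branch duration``), starting from an
11-point ancestor shaped like a left-side proximal tarsus in mm.  Under
the ``loss_expansion`` scenario the astragalus-only dataset additionally
receives a deterministic medial (-x) shift of magnitude ``delta`` of its
medial-margin landmarks on one focal branch, inherited by all descendants
— emulating a medial expansion of the astragalus after loss of the
centrale, which the combined configuration does not show because its
medial margin is already occupied.  Under ``fusion`` neither dataset is
shifted and the two are exchangeable draws.  Independent Gaussian
digitisation noise is added at the leaves.

Brownian motion runs on raw coordinates, not in Procrustes tangent space:
a deliberate transparency choice — the GPA step in the pipeline removes
the nuisance similarity components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .hypothesis_test import (
    AnalysisOptions,
    ComparisonEntry,
    compare_hypotheses,
    run_configuration,
)
from .landmark_io import (
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkScheme,
    default_tarsus_scheme,
    read_tps,
    scheme_from_yaml,
    scheme_to_yaml,
    write_tps,
)
from .tree_io import PhyloTree, parse_newick

__all__ = [
    "SimulationSpec",
    "default_simulation_tree",
    "default_ancestor_shape",
    "default_simulation_spec",
    "simulate_dataset",
    "calibrate_decision_rule",
    "CalibrationSummary",
    "write_fixture",
    "load_fixture",
]

SCENARIOS = ("fusion", "loss_expansion")

DEFAULT_TREE_NEWICK = "((t1,(t2,t3)),(t4,((t5,t6),(t7,t8))));"
DEFAULT_FOCAL_CLADE = ("t5", "t6", "t7", "t8")


def default_simulation_tree() -> PhyloTree:
    """8-taxon rooted tree, unit branch durations, focal clade t5..t8.

    Mirrors the real study design: a 3-taxon outgroup clade roots the
    tree and the focal clade's stem branch is nested inside the ingroup —
    never adjacent to the root, where a degree-2 root would make the
    split of one unrooted edge into two rooted branches arbitrary.
    """
    return parse_newick(DEFAULT_TREE_NEWICK)


def default_ancestor_shape() -> np.ndarray:
    """A left-side proximal-tarsus-like outline in mm (11 points).

    Medial is -x, dorsal +y; the medial margin (indices 1, 5, 8, 9, 10)
    sits at strongly negative x.  Roughly 20 mm wide and 12 mm tall, the
    size class of mid-sized Triassic archosauromorph astragali.
    """
    return np.array(
        [
            [8.0, 5.0],  # LM1 dorsolateral corner
            [-8.0, 4.0],  # LM2 dorsomedial corner (medial margin)
            [10.0, 0.0],  # LM3 lateral apex
            [7.0, -5.0],  # LM4 ventrolateral corner
            [0.0, -6.0],  # LM5 ventral midpoint
            [-9.0, 0.0],  # LM6 medial apex (medial margin)
            [0.0, 6.0],  # LM7 dorsal midpoint
            [9.0, -3.0],  # LM8 ventral margin of calcaneal facet
            [-7.0, -4.0],  # LM9 ventromedial corner (medial margin)
            [-8.8, 2.0],  # SL1 on the LM2-LM6 chord
            [-8.5, -2.0],  # SL2 on the LM6-LM9 chord
        ]
    )


def default_expansion_field() -> np.ndarray:
    """Unit-scale displacement field of the medial expansion (11 points).

    A medial expansion of the astragalus after loss of the centrale is not
    a rigid shift of the margin: the dorsomedial corner (LM2) displaces
    ventromedially, the medial apex (LM6) and the upper slider (SL1) move
    straight medially, the ventromedial corner (LM9) ventromedially, while
    the lower slider (SL2) displaces dorsolaterally with a smaller
    magnitude — the qualitative field the fossil optimisations recover.
    A heterogeneous field like this carries almost no similarity-transform
    component, so superimposition cannot absorb it.
    """
    f = np.zeros((11, 2))
    f[1] = np.array([-1.0, -1.0]) / np.sqrt(2)  # LM2 ventromedial
    f[5] = np.array([-1.0, 0.0])  # LM6 medial apex outward
    f[8] = np.array([-0.5, -0.866025])  # LM9 ventromedial corner
    f[9] = np.array([-1.0, 0.0])  # SL1 medial
    f[10] = np.array([0.36, 0.48])  # SL2 dorsolateral, lower magnitude
    return f


@dataclass(frozen=True)
class SimulationSpec:
    """Generative conditions for one synthetic study.

    ``sigma`` is the Brownian step scale in mm per unit branch duration,
    ``delta`` the magnitude in mm of the medial-expansion displacement
    applied on the focal branch under ``loss_expansion`` (ignored under
    ``fusion``), ``noise`` the per-landmark digitisation noise sd in mm.
    ``displacement_field`` is the (p, 2) unit-scale field that ``delta``
    multiplies; it must be zero outside the medial subset.  When omitted,
    the 11-point scheme gets the margin-expansion field of
    :func:`default_expansion_field`, any other scheme a uniform medial
    (-x) shift of the medial subset.
    """

    tree: PhyloTree
    ancestor_shape: np.ndarray
    scheme: LandmarkScheme
    focal_branch: str
    scenario: str = "loss_expansion"
    sigma: float = 0.3
    delta: float = 1.5
    noise: float = 0.05
    medial_subset: tuple[int, ...] = (1, 5, 8, 9, 10)
    displacement_field: np.ndarray | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for name in ("sigma", "delta", "noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.tree.subtended_leaves(self.focal_branch)  # raises if absent
        object.__setattr__(
            self, "ancestor_shape", np.asarray(self.ancestor_shape, float)
        )
        p = self.ancestor_shape.shape[0]
        field = self.displacement_field
        if field is None:
            if p == 11 and tuple(self.medial_subset) == (1, 5, 8, 9, 10):
                field = default_expansion_field()
            else:
                field = np.zeros((p, 2))
                field[list(self.medial_subset), 0] = -1.0
        field = np.asarray(field, float)
        if field.shape != (p, 2):
            raise ValueError(f"displacement_field must have shape {(p, 2)}")
        nonzero = np.flatnonzero(np.linalg.norm(field, axis=1) > 0)
        if not set(nonzero) <= set(self.medial_subset):
            raise ValueError(
                "displacement_field must be zero outside the medial subset"
            )
        object.__setattr__(self, "displacement_field", field)

    @property
    def effective_delta(self) -> float:
        return self.delta if self.scenario == "loss_expansion" else 0.0

    def focal_clade(self) -> tuple[str, ...]:
        return tuple(sorted(self.tree.subtended_leaves(self.focal_branch)))

    def default_options(self) -> AnalysisOptions:
        """Pipeline options matching this spec: the reference taxon is the
        first leaf (in tree order) outside the focal clade, mirroring the
        earliest-branching outgroup choice of the real study design."""
        focal = set(self.focal_clade())
        reference = next(
            n.label for n in self.tree.preorder() if n.is_leaf and n.label not in focal
        )
        return AnalysisOptions(
            reference_taxon=str(reference), focal_clade=self.focal_clade()
        )


def default_simulation_spec(
    seed: int = 42,
    scenario: str = "loss_expansion",
    sigma: float = 0.3,
    delta: float = 1.5,
    noise: float = 0.05,
) -> SimulationSpec:
    """The shipped default fixture conditions: 8 taxa, delta/sigma = 5."""
    tree = default_simulation_tree()
    scheme = default_tarsus_scheme()
    from .tree_io import find_branch

    focal = find_branch(tree, DEFAULT_FOCAL_CLADE)
    return SimulationSpec(
        tree=tree,
        ancestor_shape=default_ancestor_shape(),
        scheme=scheme,
        focal_branch=focal,
        scenario=scenario,
        sigma=sigma,
        delta=delta,
        noise=noise,
        medial_subset=tuple(scheme.subsets["medial"]),
        seed=seed,
    )


def _evolve(
    spec: SimulationSpec, rng: np.random.Generator, apply_delta: bool
) -> dict[str, np.ndarray]:
    """One Brownian realisation; returns leaf label -> (p, 2) coords."""
    p = spec.ancestor_shape.shape[0]
    leaves: dict[str, np.ndarray] = {}

    def walk(node, value: np.ndarray) -> None:
        for child in node.children:
            step = rng.normal(0.0, spec.sigma * np.sqrt(child.duration), size=(p, 2))
            v = value + step
            if apply_delta and child.id == spec.focal_branch:
                v = v + spec.effective_delta * spec.displacement_field
            if child.is_leaf:
                noisy = v + rng.normal(0.0, spec.noise, size=(p, 2))
                leaves[str(child.label)] = noisy
            else:
                walk(child, v)

    walk(spec.tree.root, spec.ancestor_shape.copy())
    return leaves


def simulate_dataset(spec: SimulationSpec) -> tuple[LandmarkDataset, LandmarkDataset]:
    """Simulate the (astragalus_plus_centrale, astragalus_only) pair.

    The two datasets are independent Brownian realisations on the same
    tree from the same ancestor — they emulate two digitisations of
    evolving structures, and under ``fusion`` (or delta = 0) they are
    exchangeable.  Only the astragalus-only dataset ever receives the
    focal-branch medial shift.  Fully reproducible from ``spec.seed``.
    """
    root_ss = np.random.SeedSequence(spec.seed)
    ss_combined, ss_only = root_ss.spawn(2)
    leaves_combined = _evolve(spec, np.random.default_rng(ss_combined), apply_delta=False)
    leaves_only = _evolve(spec, np.random.default_rng(ss_only), apply_delta=True)

    def as_dataset(leaves: dict[str, np.ndarray], label: str) -> LandmarkDataset:
        configs = [
            LandmarkConfiguration(specimen_id=lbl, coords=leaves[lbl], side="left")
            for lbl in spec.tree.leaf_labels()
        ]
        return LandmarkDataset(
            scheme=spec.scheme, configurations=configs, configuration_label=label
        )

    return (
        as_dataset(leaves_combined, "astragalus_plus_centrale"),
        as_dataset(leaves_only, "astragalus_only"),
    )


# ---------------------------------------------------------------------------
# Decision-rule calibration


@dataclass
class CalibrationSummary:
    """Scenario-recovery rates of the focal-branch decision rule.

    Each replicate pair is classified by the sign of
    ``d = medial(astragalus_only) - medial(astragalus_plus_centrale)`` on
    the focal branch: a positive ``d`` is the medial-expansion signature
    that only the loss scenario generates, a negative ``d`` points the
    other way, and a tie is inconclusive.  ``differences`` holds the full
    distribution of ``d`` across replicates.
    """

    spec_scenario: str
    n_reps: int
    fractions: dict[str, float]
    differences: np.ndarray
    replicates: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "scenario": self.spec_scenario,
            "n_reps": self.n_reps,
            "fractions": {k: float(v) for k, v in self.fractions.items()},
            "differences": [float(d) for d in self.differences],
            "replicates": self.replicates,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.replicates)


def _replicate_seeds(root_seed: int, n_reps: int) -> np.ndarray:
    """Documented per-replicate seed rule: entry i of the root
    SeedSequence's generated state, folded below 2**31."""
    state = np.random.SeedSequence(root_seed).generate_state(n_reps, dtype=np.uint64)
    return (state % np.uint64(2**31)).astype(np.int64)


def calibrate_decision_rule(
    spec: SimulationSpec,
    n_reps: int,
    options: AnalysisOptions | None = None,
) -> CalibrationSummary:
    """Run the full pipeline on ``n_reps`` replicate pairs and report how
    often each generative scenario is supported by the focal-branch rule."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    opts = options if options is not None else spec.default_options()
    seeds = _replicate_seeds(spec.seed, n_reps)
    counts = {"loss_expansion": 0, "fusion": 0, "inconclusive": 0}
    diffs = np.empty(n_reps)
    records: list[dict[str, Any]] = []
    for i, rep_seed in enumerate(seeds):
        rep_spec = replace(spec, seed=int(rep_seed))
        try:
            combined, only = simulate_dataset(rep_spec)
            res_combined = run_configuration(combined, spec.tree, opts)
            res_only = run_configuration(only, spec.tree, opts)
            entry = compare_hypotheses(res_combined, res_only)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed on replicate {i} (seed {int(rep_seed)}): {exc}"
            ) from exc
        d = entry.difference
        diffs[i] = d
        if d > 0:
            support = "loss_expansion"
        elif d < 0:
            support = "fusion"
        else:
            support = "inconclusive"
        counts[support] += 1
        records.append(
            {
                "replicate": i,
                "seed": int(rep_seed),
                "focal_combined": entry.focal_length_combined,
                "focal_astragalus_only": entry.focal_length_astragalus_only,
                "difference": d,
                "supported_scenario": support,
                "preferred_configuration": entry.preferred_configuration,
            }
        )
    fractions = {k: v / n_reps for k, v in counts.items()}
    return CalibrationSummary(
        spec_scenario=spec.scenario,
        n_reps=n_reps,
        fractions=fractions,
        differences=diffs,
        replicates=records,
    )


# ---------------------------------------------------------------------------
# Fixture files


def write_fixture(spec: SimulationSpec, path: str | Path) -> dict[str, Path]:
    """Emit a ready-to-run miniature study: two TPS files, the Newick
    tree, the landmark scheme and a run config referencing them."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    combined, only = simulate_dataset(spec)
    files = {
        "combined_tps": out / "astragalus_plus_centrale.tps",
        "astragalus_tps": out / "astragalus_only.tps",
        "tree": out / "tree.nwk",
        "scheme": out / "scheme.yaml",
        "config": out / "config.yaml",
    }
    files["combined_tps"].write_text(write_tps(combined.configurations))
    files["astragalus_tps"].write_text(write_tps(only.configurations))
    files["tree"].write_text(spec.tree.to_newick() + "\n")
    files["scheme"].write_text(scheme_to_yaml(spec.scheme))
    opts = spec.default_options()
    config = {
        "combined_tps": files["combined_tps"].name,
        "astragalus_tps": files["astragalus_tps"].name,
        "trees": {"simulated": files["tree"].name},
        "scheme": files["scheme"].name,
        "reference_taxon": opts.reference_taxon,
        "focal_clade": list(spec.focal_clade()),
        "scale_mode": opts.scale_mode,
        "slide": opts.slide,
        "ddof": opts.ddof,
        "provenance": {
            "generator": "tarsomorph.synthetic_data",
            "scenario": spec.scenario,
            "sigma": spec.sigma,
            "delta": spec.delta,
            "noise": spec.noise,
            "seed": spec.seed,
        },
    }
    files["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    return files


def load_fixture(
    config_path: str | Path,
) -> tuple[dict[str, LandmarkDataset], dict[str, PhyloTree], AnalysisOptions]:
    """Read a fixture (or any run config) back into pipeline inputs."""
    cfg_path = Path(config_path)
    if cfg_path.is_dir():
        cfg_path = cfg_path / "config.yaml"
    base = cfg_path.parent
    cfg = yaml.safe_load(cfg_path.read_text())
    scheme = scheme_from_yaml((base / cfg["scheme"]).read_text())
    datasets: dict[str, LandmarkDataset] = {}
    for key, label in (
        ("combined_tps", "astragalus_plus_centrale"),
        ("astragalus_tps", "astragalus_only"),
    ):
        configs = read_tps((base / cfg[key]).read_text())
        datasets[label] = LandmarkDataset(
            scheme=scheme, configurations=configs, configuration_label=label
        )
    trees = {
        name: parse_newick((base / rel).read_text())
        for name, rel in cfg["trees"].items()
    }
    options = AnalysisOptions(
        reference_taxon=cfg["reference_taxon"],
        focal_clade=tuple(cfg["focal_clade"]),
        scale_mode=cfg.get("scale_mode", "unit"),
        slide=bool(cfg.get("slide", True)),
        ddof=int(cfg.get("ddof", 1)),
    )
    return datasets, trees, options
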