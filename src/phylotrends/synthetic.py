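"""Synthetic barcode-survey generator with a planted dispersion gradient.

Everything the downstream pipeline consumes — a rooted ultrametric tree, a
phylogenetically conserved latent trait, local species assemblages, and a
BOLD/GBIF-style occurrence table with realistic contamination — is produced
here under one seed, with the generating truth recorded alongside.

The scientific knob is a single signed dispersion parameter ``d`` per
site × year cell:

* ``d < 0`` — environmental filtering: species are drawn with weight
  exp(−|d|·(trait − optimum)²), so assemblages are phylogenetically
  clustered (negative ses.MPD on average) because the trait evolves by
  Brownian motion and is therefore conserved;
* ``d = 0`` — uniform sampling without replacement, matching the tip-label
  randomization null exactly;
* ``d > 0`` — repulsion (limiting similarity): species are added
  sequentially with weight ∝ (min patristic distance to the current
  set)^d, yielding overdispersed assemblages (positive ses.MPD).

``d`` follows a linear model in standardized |latitude| and year,
d = β0 + β_lat·z(|lat|) + β_year·z(year) + β_int·z(|lat|)·z(year),
so a positive β_int plants the recoverable signal of phylogenetic
diversity rising through time fastest at high latitudes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from ._util import rng_for
from .phylometrics import PhyloDistanceMatrix, patristic_matrix

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "evolve_bm",
    "sample_assemblage",
    "generate_dataset",
    "default_site_grid",
    "write_dataset",
]

OCCURRENCE_COLUMNS = [
    "record_id",
    "species",
    "decimal_latitude",
    "decimal_longitude",
    "year",
    "seq_length_bp",
]

# Clean COI-5P barcode records draw their length from this range (always
# passes the 600–700 bp filter); planted length violations draw from the
# flanking ranges.
CLEAN_LENGTH_RANGE = (620, 680)
SHORT_LENGTH_RANGE = (300, 599)
LONG_LENGTH_RANGE = (701, 1200)

VIOLATION_RULES = (
    "missing_species",
    "invalid_coordinates",
    "missing_year",
    "length_out_of_range",
    "duplicate",
)


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips.

    Starting from two lineages at the root, waiting times between
    speciation events are exponential with total rate birth_rate × (number
    of extant lineages); a uniformly chosen lineage splits at each event.
    The final waiting interval (with all ``n_tips`` lineages alive) is
    included, so the expected root-to-tip height is
    (1/birth_rate) · Σ_{k=2..n} 1/k. The tree is ultrametric and tips are
    labelled sp0001… in traversal order; output is deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    first, second = root.new_child(), root.new_child()
    active: List[dendropy.Node] = [first, second]
    born = {first: 0.0, second: 0.0}
    t = 0.0
    for k in range(2, n_tips + 1):
        t += rng.exponential(1.0 / (birth_rate * k))
        if k < n_tips:
            i = int(rng.integers(len(active)))
            node = active.pop(i)
            node.edge.length = t - born.pop(node)
            left, right = node.new_child(), node.new_child()
            born[left] = born[right] = t
            active.extend([left, right])
    for node in active:
        node.edge.length = t - born[node]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(f"sp{i + 1:04d}")
    return tree


def evolve_bm(
    tree: dendropy.Tree, sigma2: float, root_value: float = 0.0, seed: int = 0
) -> Dict[str, float]:
    """Brownian-motion trait evolution along the tree.

    Each branch adds an independent Normal(0, sigma2 × branch length)
    increment to the parent value; returns tip_label → trait value.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    values = {tree.seed_node: float(root_value)}
    traits: Dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        values[node] = values[node.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf():
            traits[node.taxon.label] = values[node]
    return traits


def sample_assemblage(
    tree: dendropy.Tree,
    traits: Dict[str, float],
    dispersion: float,
    richness: int,
    seed: int,
    dmat: Optional[PhyloDistanceMatrix] = None,
) -> set:
    """Draw one assemblage of ``richness`` distinct species.

    dispersion < 0: environmental filtering — a trait optimum is drawn
    uniformly over the (standardized) trait range and species enter with
    weight exp(−|d|·(z_trait − optimum)²), via weighted sampling without
    replacement. dispersion > 0: repulsion — starting from one uniform
    species, each addition is drawn with weight ∝ (min patristic distance
    to the already-selected set)^d. dispersion = 0: uniform without
    replacement. richness = n_tips returns every species regardless of d.
    """
    labels = sorted(traits)
    n = len(labels)
    if not 2 <= richness <= n:
        raise ValueError(f"richness {richness} must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    if richness == n:
        return set(labels)
    if dispersion == 0:
        return set(rng.choice(labels, size=richness, replace=False))
    if dispersion < 0:
        tvals = np.array([traits[l] for l in labels])
        sd = tvals.std()
        tz = (tvals - tvals.mean()) / (sd if sd > 0 else 1.0)
        optimum = rng.uniform(tz.min(), tz.max())
        logw = -abs(dispersion) * (tz - optimum) ** 2
        # Gumbel-max trick: top-r keys realize weighted sampling w/o replacement
        keys = logw + rng.gumbel(size=n)
        chosen = np.argsort(keys)[-richness:]
        return {labels[i] for i in chosen}
    # repulsion
    if dmat is None:
        dmat = patristic_matrix(tree)
    idx = dmat.indices(labels)
    D = dmat.values[np.ix_(idx, idx)]
    selected = [int(rng.integers(n))]
    remaining = set(range(n)) - set(selected)
    min_dist = D[selected[0]].copy()
    while len(selected) < richness:
        cand = np.array(sorted(remaining))
        w = min_dist[cand] ** dispersion
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            probs = np.full(len(cand), 1.0 / len(cand))
        else:
            probs = w / total
        pick = int(rng.choice(cand, p=probs))
        selected.append(pick)
        remaining.discard(pick)
        min_dist = np.minimum(min_dist, D[pick])
    return {labels[i] for i in selected}


def default_site_grid(n_sites: int = 15) -> List[Tuple[float, float]]:
    """Latitudinal transect of survey sites from 60°S to 60°N (2-dp coords)."""
    lats = np.linspace(-60.0, 60.0, n_sites)
    lons = np.linspace(-150.0, 150.0, n_sites)
    return [(round(float(la), 2), round(float(lo), 2)) for la, lo in zip(lats, lons)]


@dataclass
class ScenarioConfig:
    """Generating conditions for one synthetic barcode survey.

    Defaults give a desk-scale survey: 150 species, 15 sites spanning
    ±60° latitude, 20 annual sampling campaigns, ~300 assemblages of 10–30
    species, and 5% planted violations per cleaning rule. ``dispersion_coefs``
    are (β0, β_lat, β_year, β_int) on standardized |latitude| and year; the
    default plants equatorial clustering with diversity rising through time
    at high latitudes (positive β_int).
    """

    n_species: int = 150
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0
    site_grid: List[Tuple[float, float]] = field(default_factory=default_site_grid)
    year_range: Tuple[int, int] = (2003, 2022)
    richness_distribution: Tuple[int, int] = (10, 30)
    dispersion_coefs: Tuple[float, float, float, float] = (-0.5, 0.2, 0.2, 0.6)
    contamination_rates: Dict[str, float] = field(
        default_factory=lambda: {rule: 0.05 for rule in VIOLATION_RULES}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be nonnegative")
        lo, hi = self.year_range
        if lo > hi:
            raise ValueError("year_range must be ordered")
        rmin, rmax = self.richness_distribution
        if rmin < 10:
            raise ValueError("minimum assemblage richness must be >= 10")
        if rmax > self.n_species or rmin > rmax:
            raise ValueError("richness_distribution out of range")
        for rule, rate in self.contamination_rates.items():
            if rule not in VIOLATION_RULES:
                raise ValueError(f"unknown contamination rule {rule!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"contamination rate for {rule} not in [0, 1]")
        if not self.site_grid:
            raise ValueError("site_grid must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["site_grid"] = [list(s) for s in self.site_grid]
        d["year_range"] = list(self.year_range)
        d["richness_distribution"] = list(self.richness_distribution)
        d["dispersion_coefs"] = list(self.dispersion_coefs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        kw = dict(d)
        if "site_grid" in kw:
            kw["site_grid"] = [tuple(s) for s in kw["site_grid"]]
        for key in ("year_range", "richness_distribution", "dispersion_coefs"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass
class SyntheticDataset:
    """A generated survey: occurrence table + true tree + generating truth.

    ``truth`` records the scenario, the standardization constants of the
    design grid, per-assemblage true dispersion d and richness, and the
    exact number of planted rows per violation rule — everything a
    recovery test needs to compare against on the generator's own scale.
    """

    occurrence_table: pd.DataFrame
    true_tree: dendropy.Tree
    truth: dict


def _dispersion_surface(config: ScenarioConfig) -> Tuple[pd.DataFrame, dict]:
    """Per site × year cell: the true dispersion d from the planted linear model."""
    cells = [
        (lat, lon, year)
        for (lat, lon) in config.site_grid
        for year in range(config.year_range[0], config.year_range[1] + 1)
    ]
    frame = pd.DataFrame(cells, columns=["lat", "lon", "year"])
    abs_lat = frame["lat"].abs().to_numpy(dtype=float)
    years = frame["year"].to_numpy(dtype=float)
    std = {
        "abs_lat_mean": float(abs_lat.mean()),
        "abs_lat_sd": float(abs_lat.std() or 1.0),
        "year_mean": float(years.mean()),
        "year_sd": float(years.std() or 1.0),
    }
    z_lat = (abs_lat - std["abs_lat_mean"]) / std["abs_lat_sd"]
    z_year = (years - std["year_mean"]) / std["year_sd"]
    b0, b_lat, b_year, b_int = config.dispersion_coefs
    frame["d"] = b0 + b_lat * z_lat + b_year * z_year + b_int * z_lat * z_year
    return frame, std


def _format_coord(x: float) -> str:
    return f"{x:.2f}"


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Generate the full synthetic survey described by ``config``.

    Clean rows (one per assemblage member, exact 2-dp site coordinates,
    in-range sequence length) are emitted first; then, for each violation
    rule, exactly round(rate × clean_row_count) contaminated rows are
    appended and their counts recorded in ``truth``. Contaminated rows are
    crafted to fail exactly their own rule under sequential first-fail
    charging (e.g. a length violation has a valid name, coordinates and
    year). Finally the row order is shuffled. Identical configs (including
    seed) give byte-identical outputs.
    """
    config.validate()
    root_seed = config.seed
    tree = simulate_yule_tree(config.n_species, config.birth_rate, rng_for(root_seed, "tree").integers(2**31))
    traits = evolve_bm(tree, config.bm_sigma2, seed=int(rng_for(root_seed, "traits").integers(2**31)))
    dmat = patristic_matrix(tree)
    surface, std = _dispersion_surface(config)

    rmin, rmax = config.richness_distribution
    rng_rich = rng_for(root_seed, "richness")
    rows: List[dict] = []
    assemblage_truth: List[dict] = []
    labels = sorted(traits)
    rng_len = rng_for(root_seed, "lengths")
    for i, cell in surface.iterrows():
        richness = int(rng_rich.integers(rmin, rmax + 1))
        seed_i = int(rng_for(root_seed, "assemblage", i).integers(2**31))
        members = sample_assemblage(tree, traits, float(cell["d"]), richness, seed_i, dmat=dmat)
        for sp in sorted(members):
            rows.append(
                {
                    "species": sp,
                    "decimal_latitude": _format_coord(cell["lat"]),
                    "decimal_longitude": _format_coord(cell["lon"]),
                    "year": str(int(cell["year"])),
                    "seq_length_bp": str(int(rng_len.integers(*CLEAN_LENGTH_RANGE, endpoint=True))),
                }
            )
        assemblage_truth.append(
            {
                "lat": float(cell["lat"]),
                "lon": float(cell["lon"]),
                "year": int(cell["year"]),
                "d": float(cell["d"]),
                "richness": richness,
            }
        )

    n_clean = len(rows)
    rng_viol = rng_for(root_seed, "violations")
    violation_counts = {}
    sites = config.site_grid
    y_lo, y_hi = config.year_range

    def _random_site():
        return sites[int(rng_viol.integers(len(sites)))]

    def _bad_length():
        if rng_viol.random() < 0.5:
            return int(rng_viol.integers(*SHORT_LENGTH_RANGE, endpoint=True))
        return int(rng_viol.integers(*LONG_LENGTH_RANGE, endpoint=True))

    for rule in VIOLATION_RULES:
        count = int(round(config.contamination_rates.get(rule, 0.0) * n_clean))
        violation_counts[rule] = count
        for j in range(count):
            lat, lon = _random_site()
            row = {
                "species": labels[int(rng_viol.integers(len(labels)))],
                "decimal_latitude": _format_coord(lat),
                "decimal_longitude": _format_coord(lon),
                "year": str(int(rng_viol.integers(y_lo, y_hi + 1))),
                "seq_length_bp": str(int(rng_viol.integers(*CLEAN_LENGTH_RANGE, endpoint=True))),
            }
            if rule == "missing_species":
                row["species"] = ""
            elif rule == "invalid_coordinates":
                if j % 2 == 0:
                    row["decimal_latitude"] = ""
                    row["decimal_longitude"] = ""
                else:
                    row["decimal_latitude"] = _format_coord(95.0 + float(rng_viol.random()))
            elif rule == "missing_year":
                row["year"] = ""
            elif rule == "length_out_of_range":
                row["seq_length_bp"] = str(_bad_length())
            elif rule == "duplicate":
                src = rows[int(rng_viol.integers(n_clean))]
                row = dict(src)
                row["seq_length_bp"] = str(int(rng_viol.integers(*CLEAN_LENGTH_RANGE, endpoint=True)))
            rows.append(row)

    table = pd.DataFrame(rows, columns=[c for c in OCCURRENCE_COLUMNS if c != "record_id"])
    perm = rng_for(root_seed, "shuffle").permutation(len(table))
    table = table.iloc[perm].reset_index(drop=True)
    table.insert(0, "record_id", [f"rec{i + 1:06d}" for i in range(len(table))])

    truth = {
        "config": config.to_dict(),
        "standardization": std,
        "n_clean": n_clean,
        "n_total": int(len(table)),
        "violations": violation_counts,
        "assemblages": assemblage_truth,
    }
    return SyntheticDataset(occurrence_table=table, true_tree=tree, truth=truth)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write occurrences.csv, tree.nwk and truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": out / "occurrences.csv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    dataset.occurrence_table.to_csv(paths["occurrences"], index=False)
    dataset.true_tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
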