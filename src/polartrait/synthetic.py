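"""Synthetic data with the statistical structure each pipeline stage assumes.

Every generator takes an explicit integer seed and is fully deterministic:
the same (seed, parameters) pair yields byte-identical serialized output.
Noise models follow the support of each measurement: multiplicative
lognormal for abundances and delta-15N readings (positive quantities),
additive Gaussian for growth rates.  Ground truth is returned alongside the
data so estimator recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np
import pandas as pd

from . import nitrogen
from .caas import GAP, CAASRecord, HabitatLabel, HomologCluster
from .errors import DesignError, InvalidParameterError
from .growth import GrowthSeries
from .nitrogen import IsotopeSample, michaelis_menten
from .thermal import TPCParams, tpc_value

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclasses.dataclass(frozen=True)
class SimulationTruth:
    """Planted parameters and positions for scoring estimator recovery."""

    scenario_id: str
    true_params: dict[str, float]
    planted_caas: list[tuple[str, int, str]]  # (cluster_id, 0-based column, residue)
    seed: int


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=size))


# ---------------------------------------------------------------------------
# growth


def simulate_growth_series(
    mu: float,
    n0: float,
    capacity: float,
    days: int,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    strain_id: str = "sim",
    condition: dict | None = None,
    replicate: int = 0,
) -> GrowthSeries:
    """Daily-sampled logistic growth with multiplicative lognormal noise.

    N(t) = K / (1 + ((K - n0)/n0) * exp(-mu t)); one record per day from
    day 0 through ``days``.  With a huge capacity this is plain exponential
    growth; with mu = 0 the series is constant at n0.
    """
    if n0 <= 0 or capacity <= 0:
        raise InvalidParameterError("n0 and capacity must be > 0")
    if capacity < n0:
        raise InvalidParameterError("capacity must be >= n0")
    if days < 3:
        raise InvalidParameterError("need at least 3 days of sampling")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(days + 1, dtype=float)
    n = capacity / (1.0 + ((capacity - n0) / n0) * np.exp(-mu * t))
    n = n * _lognormal_factor(rng, noise_cv, size=t.size)
    return GrowthSeries(
        strain_id=strain_id,
        condition=dict(condition or {}),
        replicate=replicate,
        times=t,
        abundances=n,
    )


def simulate_tpc_experiment(
    truth: TPCParams,
    temperatures,
    replicates: int = 4,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-temperature growth rates from a known thermal performance curve.

    One row per temperature x replicate; rate = curve value + N(0, noise_sd).
    """
    temps = np.asarray(temperatures, dtype=float)
    if np.unique(temps).size < 5:
        raise DesignError("need >=5 distinct temperatures (the curve has 4 parameters)")
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for temp in temps:
        mu = tpc_value(truth, temp)
        for rep in range(replicates):
            rows.append(
                {
                    "temperature": float(temp),
                    "replicate": rep,
                    "rate": float(mu + rng.normal(0.0, noise_sd)) if noise_sd else float(mu),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# photoperiod

#: the photoperiod gradient of the motivating design, hours of light
DEFAULT_PHOTOPERIODS = (1.0, 4.0, 8.0, 16.0, 24.0)


def arctic_reference_norm(h):
    """Saturating reaction norm peaking at continuous light (24 h)."""
    h = np.asarray(h, dtype=float)
    raw = h / (h + 4.0)
    return raw / (24.0 / 28.0)


def temperate_reference_norm(h, peak: float = 17.0):
    """Sigmoid-rise reaction norm with a maximum at ``peak`` hours and
    declining growth toward continuous light."""
    h = np.asarray(h, dtype=float)
    return np.exp(-((h - peak) ** 2) / 72.0)


def simulate_photoperiod_table(
    shapes: dict | None = None,
    photoperiods=DEFAULT_PHOTOPERIODS,
    n_strains: int = 4,
    replicates: int = 6,
    noise_cv: float = 0.05,
    base_rate: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level growth rates along a photoperiod gradient per origin.

    ``shapes`` maps origin -> callable giving the noiseless normalized curve;
    the default uses the arctic saturating and temperate peaked reference
    shapes.  Rates are base_rate * shape(h) * lognormal(cv).
    """
    if shapes is None:
        shapes = {"arctic": arctic_reference_norm, "temperate": temperate_reference_norm}
    rng = np.random.default_rng(seed)
    rows = []
    for origin, fn in shapes.items():
        for strain in range(n_strains):
            for h in photoperiods:
                mu = base_rate * float(fn(h))
                noise = _lognormal_factor(rng, noise_cv, size=replicates)
                for rep in range(replicates):
                    rows.append(
                        {
                            "strain_id": f"{origin[:1].upper()}{strain + 1}",
                            "origin": origin,
                            "photoperiod": float(h),
                            "replicate": rep,
                            "mu_max": mu * float(noise[rep]),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nitrate uptake

#: substrate gradient of the motivating design, umol NO3 L^-1
DEFAULT_SUBSTRATE_LEVELS = (0.1, 0.4, 0.8, 2.0, 10.0, 50.0, 100.0)


def default_source_atom_pct(substrate_levels) -> list[float]:
    """Source-pool atom% per level from the 1:1 (<=2 umol) / 9:1 (>2 umol)
    label ratios, diluted by the residual unlabelled nitrate."""
    out = []
    for s in substrate_levels:
        frac = 0.5 if s <= 2.0 else 0.1
        out.append(nitrogen.source_atom_percent(s, frac))
    return out


def simulate_uptake_assay(
    truth_vmax: float,
    truth_ks: float,
    substrate_levels=DEFAULT_SUBSTRATE_LEVELS,
    cells: float = 1e8,
    pn0: float = 10.0,
    source_atom_pct=None,
    duration: float = 40.0 / 60.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
    *,
    strain_id: str = "sim",
) -> list[IsotopeSample]:
    """Tracer-incubation records implied by known Michaelis-Menten kinetics.

    The true per-cell uptake V(S) is pushed through the inverse of the
    isotope mixing model to the delta-15N the analyzer would report;
    multiplicative noise is applied to delta-15N.  At zero noise, running
    the mixing model on the output returns V(S) to machine precision.
    """
    levels = np.asarray(substrate_levels, dtype=float)
    if np.any(levels <= 0):
        raise InvalidParameterError("all substrate levels must be > 0")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if source_atom_pct is None:
        source_atom_pct = default_source_atom_pct(levels)
    source_atom_pct = np.asarray(source_atom_pct, dtype=float)
    if source_atom_pct.size != levels.size:
        raise DesignError("source_atom_pct must have one entry per substrate level")
    rng = np.random.default_rng(seed)
    a0 = nitrogen.NATURAL_ABUNDANCE_ATOM_PCT
    samples = []
    for s, a_src in zip(levels, source_atom_pct):
        v_cell = michaelis_menten(s, truth_vmax, truth_ks)
        v_abs = v_cell * cells
        frac = v_abs * duration / pn0
        a_pn = a0 + frac * (a_src - a0)
        delta = nitrogen.atom_percent_to_delta(a_pn)
        for rep in range(replicates):
            samples.append(
                IsotopeSample(
                    strain_id=strain_id,
                    substrate=float(s),
                    atom_pct_source=float(a_src),
                    delta15n_particulate=float(delta * _lognormal_factor(rng, noise_cv)),
                    pon=pn0,
                    duration=duration,
                    cells=cells,
                    atom_pct_baseline=a0,
                    replicate=rep,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# CAAS

#: interleaved arctic/temperate species tree: every arctic tip is sister to a
#: temperate tip, so a residue fixed across arctic tips implies >=2
#: independent origins under parsimony
DEFAULT_TREE_NEWICK = (
    "(((Thalassiosira_gravida,Thalassiosira_rotula),"
    "(Thalassiosira_oceanica,Minidiscus_variabilis)),"
    "((Shionodiscus_bioculatus,Chaetoceros_sp),"
    "(Detonula_confervaceae,Leptocylindrus_danicus)),"
    "(Porosira_glacialis,Ditylum_brightwellii));"
)

DEFAULT_HABITATS = {
    "Thalassiosira_gravida": "arctic",
    "Thalassiosira_rotula": "temperate",
    "Thalassiosira_oceanica": "arctic",
    "Minidiscus_variabilis": "temperate",
    "Shionodiscus_bioculatus": "arctic",
    "Chaetoceros_sp": "temperate",
    "Detonula_confervaceae": "arctic",
    "Leptocylindrus_danicus": "temperate",
    "Porosira_glacialis": "arctic",
    "Ditylum_brightwellii": "temperate",
}

DEFAULT_FOCAL = ("Thalassiosira_gravida", "Thalassiosira_rotula")


def default_species_tree() -> dendropy.Tree:
    return dendropy.Tree.get(
        data=DEFAULT_TREE_NEWICK, schema="newick", preserve_underscores=True
    )


def simulate_caas_dataset(
    tree: dendropy.Tree | None = None,
    habitat_labels: dict[str, str] | None = None,
    n_clusters: int = 10,
    length: int = 300,
    n_planted: int = 5,
    source_mix: float = 0.3,
    seed: int = 0,
    *,
    substitution_prob: float = 0.02,
    window: int = 5,
    temperate_pool_size: int = 4,
    n_gap_runs: int = 2,
    gap_run_length: int = 8,
    focal: tuple[str, str] | None = None,
) -> tuple[list[HomologCluster], SimulationTruth]:
    """Homolog clusters evolved on a labelled species tree with planted CAAS.

    Background columns evolve neutrally (per-branch, per-site substitution
    probability ``substitution_prob``, uniform over the other 19 residues).
    Each planted column carries one residue fixed across all arctic tips and
    per-tip residues from a disjoint pool in the temperate tips; its +/-
    ``window`` flanks are held invariant and gap-free so the conserved-
    context check is exercised away from edge effects.  ``source_mix`` is
    the fraction of non-focal taxa labelled as metatranscriptome-derived
    (at least one per habitat is always metatranscriptome so the expression
    filter is testable).  Gap runs are inserted away from planted windows.
    """
    if tree is None:
        tree = default_species_tree()
    if habitat_labels is None:
        habitat_labels = dict(DEFAULT_HABITATS)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in taxa if t not in habitat_labels]
    if missing:
        raise DesignError(f"tree tips without habitat label: {missing}")
    by_hab = {
        hab: [t for t in taxa if habitat_labels[t] == hab]
        for hab in ("arctic", "temperate")
    }
    for hab, members in by_hab.items():
        if len(members) < 2:
            raise DesignError(
                f"habitat {hab!r} has {len(members)} taxa; need >=2 for the screen"
            )
    if n_planted > length:
        raise DesignError("cannot plant more sites than alignment columns")
    if n_planted and length < n_planted * (2 * window + 2):
        raise DesignError("alignment too short for the requested planted sites")

    if focal is None:
        focal = (
            DEFAULT_FOCAL
            if all(f in taxa for f in DEFAULT_FOCAL)
            else (by_hab["arctic"][0], by_hab["temperate"][0])
        )

    rng = np.random.default_rng(seed)

    # stable source assignment: one guaranteed metatranscriptome per habitat,
    # then a source_mix fraction of the remaining non-focal taxa
    sources = {t: "culture" for t in taxa}
    for hab in ("arctic", "temperate"):
        pool = sorted(t for t in by_hab[hab] if t not in focal)
        n_meta = max(1, int(round(source_mix * len(pool))))
        chosen = rng.choice(pool, size=min(n_meta, len(pool)), replace=False)
        for t in chosen:
            sources[t] = "metatranscriptome"
    labels = {
        t: HabitatLabel(
            taxon=t,
            habitat=habitat_labels[t],
            source=sources[t],
            is_focal=t in focal,
        )
        for t in taxa
    }

    aa = np.array(AMINO_ACIDS)
    clusters = []
    planted_truth: list[tuple[str, int, str]] = []
    for c in range(n_clusters):
        cluster_id = f"sim{c:04d}"
        # planted columns: spaced so conserved flanks never overlap
        if n_planted:
            slots = np.arange(window, length - window - 1)
            cols: list[int] = []
            attempts = 0
            while len(cols) < n_planted and attempts < 10000:
                cand = int(rng.choice(slots))
                if all(abs(cand - c0) > 2 * window for c0 in cols):
                    cols.append(cand)
                attempts += 1
            planted_cols = sorted(cols)
        else:
            planted_cols = []
        frozen = set()
        for col in planted_cols:
            frozen.update(range(col - window, col + window + 1))

        # neutral evolution along the tree
        root_seq = rng.integers(0, 20, size=length)
        seqs_idx: dict[str, np.ndarray] = {}

        def evolve(node, seq):
            for child in node.child_nodes():
                s = seq.copy()
                hits = np.flatnonzero(rng.random(length) < substitution_prob)
                for i in hits:
                    if i in frozen:
                        continue
                    s[i] = (s[i] + rng.integers(1, 20)) % 20
                if child.is_leaf():
                    seqs_idx[child.taxon.label] = s
                else:
                    evolve(child, s)

        evolve(tree.seed_node, root_seq)

        seqs = {t: aa[ix].copy() for t, ix in seqs_idx.items()}

        # plant the convergent substitutions
        for col in planted_cols:
            arctic_res = str(rng.choice(aa))
            others = [r for r in AMINO_ACIDS if r != arctic_res]
            pool = rng.choice(others, size=temperate_pool_size, replace=False)
            for t in by_hab["arctic"]:
                seqs[t][col] = arctic_res
            for t in by_hab["temperate"]:
                seqs[t][col] = str(rng.choice(pool))
            planted_truth.append((cluster_id, col, arctic_res))

        # gap runs in random members, away from planted windows
        for _ in range(n_gap_runs):
            taxon = str(rng.choice(taxa))
            for _ in range(200):
                start = int(rng.integers(0, max(length - gap_run_length, 1)))
                span = range(start, min(start + gap_run_length, length))
                if not any(i in frozen for i in span):
                    for i in span:
                        seqs[taxon][i] = GAP
                    break

        clusters.append(
            HomologCluster(
                cluster_id=cluster_id,
                members={t: "".join(seqs[t]) for t in sorted(seqs)},
                labels=labels,
                tree=tree,
            )
        )

    truth = SimulationTruth(
        scenario_id=f"caas-n{n_clusters}-L{length}-p{n_planted}",
        true_params={"substitution_prob": substitution_prob},
        planted_caas=planted_truth,
        seed=seed,
    )
    return clusters, truth


def score_caas_recovery(
    records: list[CAASRecord], truth: SimulationTruth
) -> tuple[float, float]:
    """(sensitivity, precision) of reported records against planted truth.

    A record matches a planted site when cluster and original-coordinate
    column agree.  Sensitivity is matched planted sites / planted sites;
    precision is matching records / reported records.  Both are 1.0 when
    nothing was planted and nothing reported.
    """
    planted = {(cid, col) for cid, col, _ in truth.planted_caas}
    reported = {
        (r.cluster_id, r.original_column if r.original_column is not None else r.column)
        for r in records
    }
    if not planted:
        sensitivity = 1.0
    else:
        sensitivity = len(planted & reported) / len(planted)
    if not reported:
        precision = 1.0
    else:
        precision = len(planted & reported) / len(reported)
    return sensitivity, precision
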