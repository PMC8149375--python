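"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one data type of the anchored combination-screen
study and records exactly what was planted, so downstream stages can be
tested for recovery without any external download:

* :func:`simulate_screen` -- 4PL viability curves for a drug library, alone
  and on a fixed anchor dose, with a subset of drugs given a planted
  left-shift of their combination GI50;
* :func:`simulate_dose_matrix` -- 6 x 8 inhibition matrices built under Bliss
  independence, Bliss plus a constant excess, or exact dose additivity (a
  median-effect drug "combined" with itself);
* :func:`simulate_counts` -- negative-binomial RNA-seq-like counts under a
  2 x 2 drug design with planted interaction coefficients;
* :func:`simulate_phospho` -- phosphopeptide fold changes with the substrates
  of one kinase shifted;
* :func:`simulate_network` -- a background graph plus a unique planted path
  between an upstream and a downstream node.

All generators are fully deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dose_response import DoseSeries, four_pl
from .errors import ConfigError
from .synergy import DoseMatrix, median_effect_fa

__all__ = [
    "ScreenSimConfig", "ScreenSim", "simulate_screen",
    "simulate_dose_matrix", "CountSimConfig", "simulate_counts",
    "simulate_phospho", "simulate_network", "default_dose_grid",
]


def default_dose_grid(n_doses: int = 8, low: float = 1e-9, high: float = 1e-5) -> np.ndarray:
    """Log-spaced molar dose ladder spanning a 10,000-fold range."""
    return np.logspace(np.log10(low), np.log10(high), n_doses)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Design of a synthetic anchored screen.

    ``anchor_ic25_effect`` is the inhibition fraction the anchor contributes
    on its own at its fixed screening dose; it composes with each drug's
    effect under Bliss independence for non-sensitizers, so "no interaction"
    is well defined.  Planted sensitizers have their combination curve
    left-shifted ``gi50_shift_fold``-fold in dose and its floor multiplied by
    ``sensitizer_kill_factor`` (< 1 deepens the kill): a true combination hit
    is both more potent and cytotoxic rather than merely cytostatic.  Set the
    kill factor to 1 for a pure potency shift.
    """

    n_drugs: int = 292
    n_cell_lines: int = 8
    n_doses: int = 8
    dose_grid: np.ndarray | None = None
    anchor_ic25_effect: float = 0.15
    n_sensitizers: int = 10
    gi50_shift_fold: float = 5.0
    sensitizer_kill_factor: float = 0.5
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_doses < 4:
            raise ConfigError(f"n_doses must be >= 4, got {self.n_doses}")
        if self.n_drugs < 1 or self.n_cell_lines < 1:
            raise ConfigError("n_drugs and n_cell_lines must be >= 1")
        grid = self.dose_grid
        if grid is None:
            grid = default_dose_grid(self.n_doses)
        grid = np.asarray(grid, dtype=float)
        if len(grid) != self.n_doses:
            raise ConfigError("dose_grid length must equal n_doses")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ConfigError("dose_grid must be strictly increasing and positive")
        object.__setattr__(self, "dose_grid", grid)
        if not (0 <= self.anchor_ic25_effect < 1):
            raise ConfigError(
                f"anchor_ic25_effect must be in [0, 1), got {self.anchor_ic25_effect}")
        if self.gi50_shift_fold < 1:
            raise ConfigError(f"gi50_shift_fold must be >= 1, got {self.gi50_shift_fold}")
        if not (0 < self.sensitizer_kill_factor <= 1):
            raise ConfigError(
                f"sensitizer_kill_factor must be in (0, 1], got {self.sensitizer_kill_factor}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 <= self.n_sensitizers <= self.n_drugs):
            raise ConfigError("n_sensitizers must be in [0, n_drugs]")


@dataclass
class ScreenSim:
    """Generated screen: (single, combo) series per (drug, line), truth table,
    and the anchor's per-dose inhibition (constant across the ladder)."""

    config: ScreenSimConfig
    pairs: dict[tuple[str, str], tuple[DoseSeries, DoseSeries]]
    truth: pd.DataFrame
    anchor_inhibition: np.ndarray

    @property
    def sensitizers(self) -> set[str]:
        return set(self.truth.loc[self.truth["is_sensitizer"], "drug_id"])


def simulate_screen(config: ScreenSimConfig) -> ScreenSim:
    """Generate single-agent and anchored combination viability series.

    Per drug, a library-level 4PL parameter set (potency, floor, slope) is
    drawn once and jittered per cell line.  The combination series of a
    non-sensitizer is the single-agent curve times the anchor's surviving
    fraction (Bliss independence); a sensitizer's curve is additionally
    evaluated at ``gi50_shift_fold`` times the dose, i.e. left-shifted.
    Additive Gaussian noise is applied and viability clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    grid = config.dose_grid
    drugs = [f"drug_{i:03d}" for i in range(config.n_drugs)]
    lines = [f"line_{j}" for j in range(config.n_cell_lines)]
    sensitizers = set(
        rng.choice(drugs, size=config.n_sensitizers, replace=False).tolist()
    )
    anchor_surv = 1.0 - config.anchor_ic25_effect

    pairs: dict[tuple[str, str], tuple[DoseSeries, DoseSeries]] = {}
    for drug in drugs:
        # drug-level parameters; per-line jitter keeps lines correlated
        log_ec50 = rng.uniform(np.log10(3e-8), np.log10(1e-6))
        bottom0 = rng.uniform(0.0, 0.25)
        hill = rng.uniform(0.9, 1.8)
        if drug in sensitizers:
            shift, kill = config.gi50_shift_fold, config.sensitizer_kill_factor
        else:
            shift, kill = 1.0, 1.0
        for line in lines:
            ec50 = 10 ** (log_ec50 + rng.uniform(-0.2, 0.2))
            bottom = float(np.clip(bottom0 + rng.normal(0, 0.03), 0.0, 0.4))
            v_single = four_pl(grid, 1.0, bottom, ec50, hill)
            v_combo = four_pl(grid * shift, 1.0, bottom * kill, ec50, hill) * anchor_surv
            if config.noise_sd > 0:
                v_single = v_single + rng.normal(0, config.noise_sd, size=len(grid))
                v_combo = v_combo + rng.normal(0, config.noise_sd, size=len(grid))
            v_single = np.clip(v_single, 0.0, 1.0)
            v_combo = np.clip(v_combo, 0.0, 1.0)
            pairs[(drug, line)] = (
                DoseSeries(drug, line, "alone", grid, v_single),
                DoseSeries(drug, line, "plus_anchor", grid, v_combo),
            )
    truth = pd.DataFrame(
        {"drug_id": drugs, "is_sensitizer": [d in sensitizers for d in drugs]}
    )
    anchor_inhibition = np.full(len(grid), config.anchor_ic25_effect)
    return ScreenSim(config, pairs, truth, anchor_inhibition)


def simulate_dose_matrix(
    mode: str,
    single_agent_params: dict,
    excess: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    anchor_doses=None,
    drug_doses=None,
    combination_id: str = "sim",
    cell_line: str = "line_0",
) -> tuple[DoseMatrix, dict]:
    """6 x 8 inhibition matrix with known synergy structure.

    ``mode`` is one of:

    * ``"bliss_null"``   -- cells are exactly E_A + E_B - E_A E_B;
    * ``"bliss_synergy"``-- the Bliss expectation plus ``excess``, clipped;
    * ``"sham_loewe"``   -- one median-effect drug split across both axes,
      so dose additivity (CI = 1) holds exactly.

    ``single_agent_params`` carries median-effect parameters: for the Bliss
    modes ``{"anchor": {"Dm", "m"}, "drug": {"Dm", "m"}}``; for the sham mode
    a single ``{"Dm", "m"}``.  Returns the matrix and a truth record.
    """
    if mode not in ("bliss_null", "bliss_synergy", "sham_loewe"):
        raise ConfigError(f"unknown dose-matrix mode {mode!r}")
    if not (-1.0 <= excess <= 1.0):
        raise ConfigError(f"excess must be in [-1, 1], got {excess}")
    rng = np.random.default_rng(seed)
    a_doses = np.asarray(anchor_doses if anchor_doses is not None
                         else np.logspace(-8, -5.5, 6), dtype=float)
    d_doses = np.asarray(drug_doses if drug_doses is not None
                         else np.logspace(-8.5, -5, 8), dtype=float)

    if mode == "sham_loewe":
        Dm, m = single_agent_params["Dm"], single_agent_params["m"]
        ea = median_effect_fa(a_doses, Dm, m)
        eb = median_effect_fa(d_doses, Dm, m)
        grid = median_effect_fa(a_doses[:, None] + d_doses[None, :], Dm, m)
    else:
        pa, pb = single_agent_params["anchor"], single_agent_params["drug"]
        ea = median_effect_fa(a_doses, pa["Dm"], pa["m"])
        eb = median_effect_fa(d_doses, pb["Dm"], pb["m"])
        grid = ea[:, None] + eb[None, :] - ea[:, None] * eb[None, :]
        if mode == "bliss_synergy":
            grid = grid + excess
    if noise_sd > 0:
        grid = grid + rng.normal(0, noise_sd, size=grid.shape)
    grid = np.clip(grid, 0.0, 1.0)
    matrix = DoseMatrix(combination_id, cell_line, a_doses, d_doses, grid, ea, eb)
    truth = {"mode": mode, "excess": excess if mode == "bliss_synergy" else 0.0}
    return matrix, truth


@dataclass(frozen=True)
class CountSimConfig:
    """Negative-binomial count simulation under the 2 x 2 drug design
    (vehicle, drug d, drug c, d+c), ``n_reps`` replicates per arm.

    Variance follows the standard RNA-seq convention
    var = mu + dispersion * mu^2; per-sample size factors are log-normal
    around 1.  A fraction ``frac_interaction`` of genes receives an
    interaction coefficient of magnitude ``beta_dc_magnitude`` (log2 scale,
    random sign).
    """

    n_genes: int = 2000
    n_reps: int = 3
    mean_expression: float = 100.0
    dispersion: float = 0.05
    frac_interaction: float = 0.0
    beta_dc_magnitude: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_reps, (int, np.integer)):
            raise ConfigError(f"n_reps must be an integer, got {self.n_reps!r}")
        if self.n_reps < 2:
            raise ConfigError(f"n_reps must be >= 2, got {self.n_reps}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if not (0 <= self.frac_interaction <= 1):
            raise ConfigError(
                f"frac_interaction must be in [0, 1], got {self.frac_interaction}")
        if self.mean_expression <= 0:
            raise ConfigError("mean_expression must be positive")


def simulate_counts(config: CountSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, design, truth).

    ``counts`` is genes x samples; ``design`` has one row per sample with
    binary ``x_d``, ``x_c`` and their product ``x_dc``; ``truth`` records the
    per-gene coefficients (log2 scale), the planted-interaction flag, and the
    per-sample size factors (as an attribute on the design table).
    """
    rng = np.random.default_rng(config.seed)
    arms = [(0, 0), (1, 0), (0, 1), (1, 1)]
    sample_arms = [arm for arm in arms for _ in range(config.n_reps)]
    samples = [f"s{k:02d}_d{xd}c{xc}" for k, (xd, xc) in enumerate(sample_arms)]
    design = pd.DataFrame(
        {"sample": samples,
         "x_d": [a[0] for a in sample_arms],
         "x_c": [a[1] for a in sample_arms]},
    ).set_index("sample")
    design["x_dc"] = design["x_d"] * design["x_c"]

    n = config.n_genes
    genes = [f"gene_{i:04d}" for i in range(n)]
    beta0 = np.log2(config.mean_expression) + rng.normal(0, 1.0, size=n)
    beta_d = rng.normal(0, 0.5, size=n)
    beta_c = rng.normal(0, 0.5, size=n)
    n_planted = int(round(config.frac_interaction * n))
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=n_planted, replace=False)] = True
    beta_dc = np.where(
        planted, rng.choice([-1.0, 1.0], size=n) * config.beta_dc_magnitude, 0.0)

    size_factors = np.exp(rng.normal(0, 0.1, size=len(samples)))
    size_factors /= np.exp(np.mean(np.log(size_factors)))  # geometric mean 1

    X = design[["x_d", "x_c", "x_dc"]].to_numpy(dtype=float)
    log2_mu = (
        beta0[:, None]
        + np.outer(beta_d, X[:, 0])
        + np.outer(beta_c, X[:, 1])
        + np.outer(beta_dc, X[:, 2])
    )
    mu = size_factors[None, :] * 2.0 ** log2_mu
    if config.dispersion < 1e-10:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame(
        {"gene": genes, "beta_0": beta0, "beta_d": beta_d, "beta_c": beta_c,
         "beta_dc": beta_dc, "has_interaction": planted}
    ).set_index("gene")
    design.attrs["size_factors"] = pd.Series(size_factors, index=samples)
    return counts_df, design, truth


def simulate_phospho(
    n_peptides: int,
    kinase_sets: dict[str, list[str]],
    planted_kinase: str | None,
    shift: float,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[pd.Series, dict]:
    """Phosphopeptide fold changes with one kinase's substrates shifted.

    The peptide universe is the union of all substrate sets padded with
    background peptides up to ``n_peptides``.  Non-substrate fold changes are
    zero-centred Gaussian noise; the planted kinase's substrates receive the
    constant offset ``shift`` on top.
    """
    if planted_kinase is not None and planted_kinase not in kinase_sets:
        raise ConfigError(
            f"unknown kinase {planted_kinase!r}; available: {sorted(kinase_sets)}")
    if not np.isfinite(shift):
        raise ConfigError("shift must be finite")
    rng = np.random.default_rng(seed)
    universe: list[str] = []
    seen = set()
    for members in kinase_sets.values():
        for p in members:
            if p not in seen:
                seen.add(p)
                universe.append(p)
    i = 0
    while len(universe) < n_peptides:
        pep = f"pep_{i:05d}"
        if pep not in seen:
            universe.append(pep)
            seen.add(pep)
        i += 1
    fc = pd.Series(rng.normal(0, noise_sd, size=len(universe)), index=universe,
                   name="fold_change")
    if planted_kinase is not None:
        fc.loc[list(kinase_sets[planted_kinase])] += shift
    truth = {"planted_kinase": planted_kinase, "shift": shift}
    return fc, truth


def simulate_network(
    n_nodes: int,
    planted_path_length: int,
    seed: int = 0,
    background_density: float = 0.02,
) -> tuple[nx.Graph, dict[str, float], dict[str, float], list[str]]:
    """Background graph plus a unique planted path.

    The path has ``planted_path_length`` edges from an upstream node ``U`` to
    a downstream node ``D``; its interior nodes are the ground-truth linkers.
    Background edges are drawn among the non-path nodes, and the upstream
    endpoint is additionally wired into the background, so the planted path
    remains the unique route between U and D.
    Returns (graph, upstream weights, downstream weights, truth linkers).
    """
    if planted_path_length < 1:
        raise ConfigError("planted_path_length must be >= 1")
    if n_nodes < planted_path_length + 1:
        raise ConfigError(
            f"n_nodes={n_nodes} too small for a path of {planted_path_length} edges")
    rng = np.random.default_rng(seed)
    path_nodes = [f"n{0:03d}"] + [f"n{i:03d}" for i in range(1, planted_path_length + 1)]
    other = [f"n{i:03d}" for i in range(planted_path_length + 1, n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(path_nodes + other)
    nx.add_path(g, path_nodes)
    interior = path_nodes[1:-1]
    for i, a in enumerate(other):
        for b in other[i + 1:]:
            if rng.random() < background_density:
                g.add_edge(a, b)
    for b in other:
        if rng.random() < background_density:
            g.add_edge(path_nodes[0], b)
    upstream = {path_nodes[0]: 1.0}
    downstream = {path_nodes[-1]: 1.0}
    return g, upstream, downstream, list(interior)
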