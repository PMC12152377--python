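"""Synthetic combination screens with known ground truth.

The generator produces a small, fully self-consistent analogue of a public
combination-screen corpus: a screen table (monotherapy dose series and
two-drug dose matrices with replicate noise), a gene-expression matrix, drug
annotation tables (binary fingerprints, numeric descriptors, drug-target
mapping), and a CMax table — together with the generating parameters, so
every downstream computation can be checked against an analytic oracle.

World model
-----------
* Each cell line has a latent vector z (dimension ``latent_dim``);
  expression is a linear read-out of z plus gene-level noise, so PCA on
  expression recovers the latent space.
* Each drug carries a random binary fingerprint; its latent *effect
  vector* w is a fixed linear function of the fingerprint, so drug
  behaviour is learnable from structure features.
* Monotherapy response follows a three-parameter logistic viability curve
  whose inflection concentration shifts with the cell-drug match
  ``z . w``: matched cells are more sensitive.  This makes cell-blind
  generalization possible from expression.
* Combination response is Bliss-style independence — the product of the
  two monotherapy viabilities — optionally multiplied by a localized
  synergy dip (a Gaussian bump on the log-concentration plane), giving
  some pairs a window of extra effect below their maximal doses.
* Measured inhibition is 100 * (1 - viability) plus Gaussian replicate
  noise (default standard deviation 7, matching the replicate scatter of
  large public screens), clipped to the valid range [-200, 200].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import _f3pl
from .screen import CMaxTable, ScreenTable

__all__ = [
    "SyntheticWorldConfig",
    "GroundTruth",
    "SyntheticWorld",
    "generate_world",
    "ground_truth_measures",
]


@dataclass
class SyntheticWorldConfig:
    """Knobs of the synthetic world; defaults give a desk-scale screen."""

    n_cells: int = 30
    n_drugs: int = 10
    n_combinations: int = 15
    latent_dim: int = 8
    n_genes: int = 200
    doses_per_drug: int = 6       # >= 5 so monotherapy curves are fittable
    replicates: int = 1
    noise_sd: float = 7.0         # inhibition units, replicate scatter
    synergy_fraction: float = 0.3
    cmax_quantile: float = 0.8    # CMax position within the screened log-range
    potency_coupling: float = 1.0 # strength of the z.w shift of log-potency
    expression_noise_sd: float = 0.1
    fingerprint_len: int = 64
    n_descriptors: int = 24
    n_target_molecules: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doses_per_drug < 5:
            raise ValueError("doses_per_drug must be >= 5 (curves need 5 points)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.synergy_fraction <= 1:
            raise ValueError("synergy_fraction must be in [0, 1]")
        max_pairs = self.n_drugs * (self.n_drugs - 1) // 2
        if self.n_combinations > max_pairs:
            raise ValueError(
                f"n_combinations={self.n_combinations} exceeds the "
                f"{max_pairs} possible drug pairs"
            )


@dataclass
class Interaction:
    """Localized synergy dip on the log-concentration plane of one pair."""

    amplitude: float   # 0 = pure Bliss independence
    mu_log_a: float
    mu_log_b: float
    sigma_log: float

    def modifier(self, conc_a, conc_b):
        if self.amplitude == 0:
            return np.ones(np.broadcast(np.asarray(conc_a), np.asarray(conc_b)).shape)
        la = np.log(np.maximum(conc_a, 1e-300))
        lb = np.log(np.maximum(conc_b, 1e-300))
        bump = np.exp(
            -((la - self.mu_log_a) ** 2 + (lb - self.mu_log_b) ** 2)
            / (2 * self.sigma_log**2)
        )
        out = 1.0 - self.amplitude * bump
        # zero dose of either drug cannot produce interaction
        zero = (np.asarray(conc_a) == 0) | (np.asarray(conc_b) == 0)
        return np.where(zero, 1.0, out)


@dataclass
class GroundTruth:
    """Generating parameters: the oracle for every derived quantity."""

    cell_latent: pd.DataFrame            # cells x latent_dim
    drug_params: pd.DataFrame            # per drug: b, c, e0, cmax
    log_e: pd.DataFrame                  # cells x drugs: true log inflection
    doses: dict[str, np.ndarray]         # per drug: screened µM dose ladder
    interactions: dict[tuple[str, str], Interaction]
    drug_effect: pd.DataFrame            # drugs x latent_dim effect vectors
    expression_loadings: np.ndarray      # n_genes x latent_dim

    def mono_viability(self, cell: str, drug: str, conc):
        p = self.drug_params.loc[drug]
        e = float(np.exp(self.log_e.loc[cell, drug]))
        arr = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            v = np.where(arr > 0, _f3pl(np.maximum(arr, 1e-300), p["b"], p["c"], e), 1.0)
        return float(v) if arr.ndim == 0 else v

    def combo_viability(self, cell: str, drug_a: str, drug_b: str, conc_a, conc_b):
        key = (drug_a, drug_b) if (drug_a, drug_b) in self.interactions else (drug_b, drug_a)
        if key != (drug_a, drug_b):
            conc_a, conc_b = conc_b, conc_a
            drug_a, drug_b = drug_b, drug_a
        inter = self.interactions[key]
        v = (
            self.mono_viability(cell, drug_a, conc_a)
            * self.mono_viability(cell, drug_b, conc_b)
            * inter.modifier(conc_a, conc_b)
        )
        return np.clip(v, 0.0, 1.0)


@dataclass
class SyntheticWorld:
    """Everything a screen-analysis pipeline consumes, plus the oracle."""

    config: SyntheticWorldConfig
    screen: ScreenTable                  # raw µM scale, pre-averaging
    expression: pd.DataFrame             # genes x cells
    fingerprints: pd.DataFrame           # drugs x bits (binary)
    descriptors: pd.DataFrame            # drugs x numeric descriptors
    targets: dict[str, frozenset]        # drug -> target molecules
    cmax: CMaxTable
    truth: GroundTruth

    @property
    def cells(self) -> list[str]:
        return list(self.truth.cell_latent.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.truth.drug_params.index)


def generate_world(cfg: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic screen world, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    cells = [f"CL{i:03d}" for i in range(cfg.n_cells)]
    drugs = [f"D{i:02d}" for i in range(cfg.n_drugs)]
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # --- latent structure ------------------------------------------------
    z = rng.standard_normal((cfg.n_cells, cfg.latent_dim))
    fingerprints = rng.integers(0, 2, size=(cfg.n_drugs, cfg.fingerprint_len))
    proj = rng.standard_normal((cfg.fingerprint_len, cfg.latent_dim))
    w = (fingerprints - 0.5) @ proj
    w /= np.linalg.norm(w, axis=1, keepdims=True)  # unit effect vectors

    # --- per-drug curve parameters and dose ladders ----------------------
    b = rng.uniform(0.8, 2.0, cfg.n_drugs)
    c = rng.uniform(0.0, 0.3, cfg.n_drugs)
    log_e0 = rng.uniform(np.log(0.1), np.log(10.0), cfg.n_drugs)  # µM
    # cell-specific potency: matched cells (z.w > 0) are more sensitive
    match = z @ w.T  # cells x drugs, sd ~ 1
    log_e = log_e0[None, :] - cfg.potency_coupling * match

    half_log = 0.5 * np.log(10.0)
    offsets = (np.arange(cfg.doses_per_drug) - (cfg.doses_per_drug - 1) / 2) * half_log
    doses = {d: np.exp(log_e0[j] + offsets) for j, d in enumerate(drugs)}

    cmax_vals = {}
    for d in drugs:
        lo, hi = np.log(doses[d][0]), np.log(doses[d][-1])
        cmax_vals[d] = float(np.exp(lo + cfg.cmax_quantile * (hi - lo)))

    # --- combination choices and interactions ----------------------------
    all_pairs = [(drugs[i], drugs[j]) for i in range(cfg.n_drugs) for j in range(i + 1, cfg.n_drugs)]
    pair_idx = rng.choice(len(all_pairs), size=cfg.n_combinations, replace=False)
    pairs = [all_pairs[i] for i in sorted(pair_idx)]
    n_synergy = int(round(cfg.synergy_fraction * cfg.n_combinations))
    synergy_flags = np.zeros(cfg.n_combinations, dtype=bool)
    synergy_flags[rng.choice(cfg.n_combinations, size=n_synergy, replace=False)] = True
    interactions: dict[tuple[str, str], Interaction] = {}
    for (da, db), syn in zip(pairs, synergy_flags):
        if syn:
            # dip centered inside the screened log-range of each drug
            mu_a = rng.uniform(np.log(doses[da][1]), np.log(doses[da][-2]))
            mu_b = rng.uniform(np.log(doses[db][1]), np.log(doses[db][-2]))
            interactions[(da, db)] = Interaction(
                amplitude=float(rng.uniform(0.2, 0.5)),
                mu_log_a=float(mu_a),
                mu_log_b=float(mu_b),
                sigma_log=half_log,
            )
        else:
            interactions[(da, db)] = Interaction(0.0, 0.0, 0.0, 1.0)

    truth = GroundTruth(
        cell_latent=pd.DataFrame(z, index=cells),
        drug_params=pd.DataFrame(
            {"b": b, "c": c, "e0": np.exp(log_e0), "cmax": [cmax_vals[d] for d in drugs]},
            index=drugs,
        ),
        log_e=pd.DataFrame(log_e, index=cells, columns=drugs),
        doses=doses,
        interactions=interactions,
        drug_effect=pd.DataFrame(w, index=drugs),
        expression_loadings=None,  # set below
    )

    # --- screen entries ---------------------------------------------------
    rows: list[tuple] = []
    for cell in cells:
        for d in drugs:
            v = truth.mono_viability(cell, d, doses[d])
            for conc, vi in zip(doses[d], v):
                for _ in range(cfg.replicates):
                    rows.append((cell, d, None, conc, 0.0, 100.0 * (1.0 - vi)))
        for da, db in pairs:
            ca, cb = np.meshgrid(doses[da], doses[db], indexing="ij")
            v = truth.combo_viability(cell, da, db, ca, cb)
            for a_, b_, vi in zip(ca.ravel(), cb.ravel(), v.ravel()):
                for _ in range(cfg.replicates):
                    rows.append((cell, da, db, float(a_), float(b_), 100.0 * (1.0 - vi)))
    df = pd.DataFrame(
        rows,
        columns=["cell_line", "drug_row", "drug_col", "conc_row", "conc_col", "inhibition"],
    )
    if cfg.noise_sd > 0:
        df["inhibition"] = df["inhibition"] + rng.normal(0.0, cfg.noise_sd, len(df))
    df["inhibition"] = df["inhibition"].clip(-200.0, 200.0)
    screen = ScreenTable(df, scale="raw")

    # --- expression, descriptors, targets ---------------------------------
    loadings = rng.standard_normal((cfg.n_genes, cfg.latent_dim))
    expr = loadings @ z.T + cfg.expression_noise_sd * rng.standard_normal(
        (cfg.n_genes, cfg.n_cells)
    )
    expression = pd.DataFrame(expr, index=genes, columns=cells)
    truth.expression_loadings = loadings

    desc_proj = rng.standard_normal((cfg.fingerprint_len, cfg.n_descriptors))
    desc = (fingerprints - 0.5) @ desc_proj + 0.05 * rng.standard_normal(
        (cfg.n_drugs, cfg.n_descriptors)
    )
    descriptors = pd.DataFrame(
        desc, index=drugs, columns=[f"desc_{i}" for i in range(cfg.n_descriptors)]
    )
    fp_df = pd.DataFrame(
        fingerprints, index=drugs,
        columns=[f"bit_{i}" for i in range(cfg.fingerprint_len)],
    )
    molecules = [f"TGT{i:02d}" for i in range(cfg.n_target_molecules)]
    tmat = rng.random((cfg.n_drugs, cfg.n_target_molecules)) < 0.3
    targets = {
        d: frozenset(m for m, hit in zip(molecules, tmat[j]) if hit)
        for j, d in enumerate(drugs)
    }

    return SyntheticWorld(
        config=cfg,
        screen=screen,
        expression=expression,
        fingerprints=fp_df,
        descriptors=descriptors,
        targets=targets,
        cmax=CMaxTable(cmax_vals),
        truth=truth,
    )


def ground_truth_measures(
    world: SyntheticWorld, dense_n: int = 201
) -> pd.DataFrame:
    """Analytic sensitivity measures from the generating parameters.

    Monotherapy IC50 and CMax viability come from the true curve in closed
    form; the true combination CMax viability is the minimum of the true
    surface over the CMax box, found by dense evaluation on a
    ``dense_n x dense_n`` lattice.  Returns a tidy frame
    (cell_line, treatment, measure, value).
    """
    truth = world.truth
    records = []
    for cell in world.cells:
        for d in world.drugs:
            p = truth.drug_params.loc[d]
            e = float(np.exp(truth.log_e.loc[cell, d]))
            cmax = float(p["cmax"])
            # IC50: closed-form inversion, undefined when asymptote >= 0.5
            if p["c"] < 0.5:
                gap = (1.0 - p["c"]) / (0.5 - p["c"]) - 1.0
                ic50 = e * gap ** (1.0 / p["b"])
            else:
                ic50 = np.nan
            records.append((cell, d, "ic50", ic50))
            records.append(
                (cell, d, "cmax_viability", truth.mono_viability(cell, d, cmax))
            )
        for (da, db) in truth.interactions:
            ca = np.linspace(0.0, truth.drug_params.loc[da, "cmax"], dense_n)
            cb = np.linspace(0.0, truth.drug_params.loc[db, "cmax"], dense_n)
            aa, bb = np.meshgrid(ca, cb, indexing="ij")
            v = truth.combo_viability(cell, da, db, aa, bb)
            records.append(
                (cell, "+".join(sorted((da, db))), "combination_cmax_viability",
                 float(np.min(v)))
            )
    return pd.DataFrame(
        records, columns=["cell_line", "treatment", "measure", "value"]
    )
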