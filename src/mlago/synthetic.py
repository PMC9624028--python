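"""Desk-scale synthetic fixtures: toy pathways and structured K_m tables.

Two generators make every stage of the pipeline testable without
external downloads:

* ``make_toy_pathway`` builds an irreversible Michaelis-Menten chain
  S0 -> S1 -> ... -> Sn (constant inflow into S0, first-order sink from
  Sn) with known true parameters, standing in for the realistic
  metabolism benchmark models. The boundary conditions guarantee a
  unique stable steady state, so simulations stay fast and mildly stiff.

* ``make_synthetic_km_table`` draws K_m records from an additive
  random-effects model on log10 scale: each EC hierarchy level, compound
  and organism category carries a normal effect, plus residual noise.
  This is the simplest structure in which the EC hierarchy and compound
  identity carry most of the signal, and it admits a closed-form best
  achievable held-out R² = Σσ²_effects / (Σσ²_effects + σ²_ε) for
  oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mlago.kinetics import Condition, KineticModel
from mlago.km_dataset import KmTable

DEFAULT_KM_RANGE = (0.01, 10.0)  # mM, the bulk of measured K_m's
DEFAULT_VMAX_RANGE = (0.1, 10.0)  # concentration / time


@dataclass
class ToyPathwaySpec:
    n_reactions: int = 5
    vmax_range: tuple[float, float] = DEFAULT_VMAX_RANGE
    km_range: tuple[float, float] = DEFAULT_KM_RANGE
    inflow: float = 1.0
    sink_rate: float = 1.0
    initial_substrate: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < 1:
            raise ValueError("need at least one reaction")
        lo, hi = self.km_range
        if not (1e-5 <= lo < hi <= 1e3):
            raise ValueError("km_range must lie within the global search bounds [1e-5, 1e3] mM")


def make_toy_pathway(spec: ToyPathwaySpec) -> tuple[KineticModel, np.ndarray]:
    """Michaelis-Menten chain with known true parameters.

    States S0..Sn; reaction i consumes S(i-1) at rate
    v_i = Vmax_i * S / (Km_i + S). dS0/dt adds the constant inflow,
    dSn/dt subtracts the first-order sink k_out * Sn. Parameters are
    drawn log-uniformly from the spec ranges (seeded); the parameter
    vector is ordered (Vmax_1..n, Km_1..n, k_out) with the K_m block
    flagged in ``km_mask``. Synthetic (EC, compound, organism)
    annotations are attached per reaction for predictor queries.
    """
    n = spec.n_reactions
    rng = np.random.default_rng(spec.seed)

    def log_uniform(lo, hi, size):
        return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size)

    vmax = log_uniform(*spec.vmax_range, n)
    km = log_uniform(*spec.km_range, n)
    p_true = np.concatenate([vmax, km, [spec.sink_rate]])

    state_names = [f"S{i}" for i in range(n + 1)]
    parameter_names = [f"Vmax{i+1}" for i in range(n)] + [f"Km{i+1}" for i in range(n)] + ["k_out"]
    km_mask = np.array([False] * n + [True] * n + [False])
    inflow = spec.inflow

    def rhs(t, x, p):
        vm, k, k_out = p[:n], p[n : 2 * n], p[2 * n]
        s = np.maximum(x[:-1], 0.0)
        v = vm * s / (k + s)
        dx = np.empty(n + 1)
        dx[0] = inflow - v[0]
        dx[1:] = v
        dx[1:-1] -= v[1:]
        dx[-1] -= k_out * x[-1]
        return dx

    x0 = np.zeros(n + 1)
    x0[0] = spec.initial_substrate
    annotations = {
        f"Km{i+1}": (f"1.1.1.{i+1}", f"C{i+1:05d}", "T00001") for i in range(n)
    }
    model = KineticModel(
        name=f"toy_chain_{n}",
        state_names=state_names,
        parameter_names=parameter_names,
        km_mask=km_mask,
        rhs=rhs,
        conditions={"default": Condition("default", x0)},
        annotations=annotations,
    )
    return model, p_true


DEFAULT_TOY_TIMEPOINTS = np.linspace(0.5, 10.0, 10)


@dataclass
class SyntheticKmSpec:
    """Hierarchical random-effects generator for K_m tables.

    Category counts are nested (level sizes non-decreasing down the EC
    hierarchy). Effect standard deviations are on log10-mM scale; the
    defaults put the dominant signal on the full 4-digit EC code and the
    compound, mirroring where the measured-data signal lives, with a
    residual spread of about half a decade.
    """

    n_entries: int = 2000
    n_ec1: int = 6
    n_ec12: int = 12
    n_ec123: int = 24
    n_ec1234: int = 60
    n_compounds: int = 40
    n_organisms: int = 20
    sigma_ec1: float = 0.1
    sigma_ec12: float = 0.15
    sigma_ec123: float = 0.2
    sigma_ec1234: float = 0.6
    sigma_compound: float = 0.4
    sigma_organism: float = 0.1
    sigma_noise: float = 0.5
    mu: float = -0.5  # grand mean of log10(K_m/mM); bulk of K_m's sit below 1 mM
    seed: int = 0

    def __post_init__(self):
        sizes = (self.n_ec1, self.n_ec12, self.n_ec123, self.n_ec1234)
        if any(a > b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("EC level category counts must be non-decreasing")
        sigmas = (self.sigma_ec1, self.sigma_ec12, self.sigma_ec123, self.sigma_ec1234,
                  self.sigma_compound, self.sigma_organism, self.sigma_noise)
        if any(s < 0 for s in sigmas):
            raise ValueError("all standard deviations must be >= 0")

    @property
    def signal_variance(self) -> float:
        return (self.sigma_ec1**2 + self.sigma_ec12**2 + self.sigma_ec123**2
                + self.sigma_ec1234**2 + self.sigma_compound**2 + self.sigma_organism**2)

    @property
    def theoretical_r2_ceiling(self) -> float:
        """Best achievable held-out R²: signal / (signal + noise) variance."""
        s = self.signal_variance
        return s / (s + self.sigma_noise**2)


def _nested_ec_codes(spec: SyntheticKmSpec) -> list[str]:
    """n_ec1234 EC codes whose prefixes realize the requested level counts."""
    ec12 = [(i % spec.n_ec1, i // spec.n_ec1) for i in range(spec.n_ec12)]
    ec123 = [(ec12[i % spec.n_ec12], i // spec.n_ec12) for i in range(spec.n_ec123)]
    codes = []
    for i in range(spec.n_ec1234):
        (l1, l2), l3 = ec123[i % spec.n_ec123]
        codes.append(f"{l1 + 1}.{l2 + 1}.{l3 + 1}.{i // spec.n_ec123 + 1}")
    return codes


def make_synthetic_km_table(spec: SyntheticKmSpec) -> tuple[KmTable, dict]:
    """Draw a K_m table from the additive random-effects model.

    Per entry: sample an EC code, compound and organism uniformly; set
    log10 K_m = mu + sum of the six category effects + residual noise.
    Effects are drawn once per category from centered normals with the
    spec's standard deviations. Returns the table and the truth record
    {'effects': per-level dicts, 'log10_km_clean': noise-free targets}.
    """
    rng = np.random.default_rng(spec.seed)
    ec_codes = _nested_ec_codes(spec)
    compounds = [f"C{i+1:05d}" for i in range(spec.n_compounds)]
    organisms = [f"T{i+1:05d}" for i in range(spec.n_organisms)]

    levels = {
        "ec1": sorted({c.split(".")[0] for c in ec_codes}),
        "ec12": sorted({".".join(c.split(".")[:2]) for c in ec_codes}),
        "ec123": sorted({".".join(c.split(".")[:3]) for c in ec_codes}),
        "ec1234": sorted(set(ec_codes)),
        "compound": compounds,
        "organism": organisms,
    }
    sigmas = {
        "ec1": spec.sigma_ec1, "ec12": spec.sigma_ec12, "ec123": spec.sigma_ec123,
        "ec1234": spec.sigma_ec1234, "compound": spec.sigma_compound,
        "organism": spec.sigma_organism,
    }
    effects = {
        level: {cat: sigmas[level] * rng.standard_normal() for cat in cats}
        for level, cats in levels.items()
    }

    ec_draw = rng.integers(0, len(ec_codes), spec.n_entries)
    comp_draw = rng.integers(0, spec.n_compounds, spec.n_entries)
    org_draw = rng.integers(0, spec.n_organisms, spec.n_entries)
    rows, clean = [], []
    for e, c, o in zip(ec_draw, comp_draw, org_draw):
        ec = ec_codes[e]
        parts = ec.split(".")
        compound, organism = compounds[c], organisms[o]
        y = (spec.mu
             + effects["ec1"][parts[0]]
             + effects["ec12"][".".join(parts[:2])]
             + effects["ec123"][".".join(parts[:3])]
             + effects["ec1234"][ec]
             + effects["compound"][compound]
             + effects["organism"][organism])
        clean.append(y)
        rows.append((ec, compound, organism, y))
    noise = spec.sigma_noise * rng.standard_normal(spec.n_entries)
    df = pd.DataFrame(rows, columns=["ec_number", "compound_id", "organism_id", "km_mM"])
    df["km_mM"] = 10.0 ** (df["km_mM"].to_numpy() + noise)
    table = KmTable(df, provenance=f"synthetic random-effects table (seed {spec.seed})")
    truth = {"effects": effects, "log10_km_clean": np.asarray(clean), "spec": spec}
    return table, truth


def make_km_table_for_model(
    model: KineticModel, p_true: np.ndarray, n_per_km: int = 30,
    sigma: float = 0.25, seed: int = 0,
) -> KmTable:
    """A K_m table whose entries scatter around a toy model's true K_m's.

    Each annotated K_m contributes ``n_per_km`` records with log10 values
    centered on the truth (SD ``sigma``) under its own (EC, compound,
    organism) triple, so a predictor trained on the table yields
    references near the true values — the full-pipeline recovery fixture.
    """
    rng = np.random.default_rng(seed)
    km_idx = {n: i for i, n in enumerate(model.parameter_names)}
    rows = []
    for km_name, (ec, compound, organism) in model.annotations.items():
        q_true = np.log10(p_true[km_idx[km_name]])
        for j in range(n_per_km):
            y = q_true + sigma * rng.standard_normal()
            # vary the organism so records are not all duplicates of one triple
            rows.append((ec, compound, f"T{j+1:05d}", 10.0**y))
    df = pd.DataFrame(rows, columns=["ec_number", "compound_id", "organism_id", "km_mM"])
    return KmTable(df, provenance="synthetic table centered on toy-model truth")


# ---------------------------------------------------------------------------
# SBML fixture writer (subset matching the reader in mlago.kinetics)

_SBML_TEMPLATE_HEADER = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="{model_id}">
    <listOfCompartments>
      <compartment id="cell" size="1" constant="true"/>
    </listOfCompartments>
"""


def write_toy_sbml(spec: ToyPathwaySpec, path: str | Path) -> tuple[KineticModel, np.ndarray]:
    """Write the toy chain as a minimal SBML Level 3 file.

    Returns the equivalent native (model, p_true) pair so tests can check
    cross-implementation agreement between the SBML loader's simulation
    and the native right-hand side.
    """
    model, p_true = make_toy_pathway(spec)
    n = spec.n_reactions
    vmax, km = p_true[:n], p_true[n : 2 * n]
    x0 = model.conditions["default"].initial_state

    parts = [_SBML_TEMPLATE_HEADER.format(model_id=model.name)]
    parts.append("    <listOfSpecies>\n")
    for name, conc in zip(model.state_names, map(float, x0)):
        parts.append(
            f'      <species id="{name}" compartment="cell" initialConcentration="{conc}"'
            ' hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>\n'
        )
    parts.append("    </listOfSpecies>\n    <listOfParameters>\n")
    for i in range(n):
        parts.append(f'      <parameter id="Vmax{i+1}" value="{float(vmax[i])!r}" constant="true"/>\n')
        parts.append(f'      <parameter id="Km{i+1}" value="{float(km[i])!r}" constant="true"/>\n')
    parts.append(f'      <parameter id="k_out" value="{spec.sink_rate}" constant="true"/>\n')
    parts.append(f'      <parameter id="J_in" value="{spec.inflow}" constant="true"/>\n')
    parts.append("    </listOfParameters>\n    <listOfReactions>\n")

    # constant inflow into S0
    parts.append(
        '      <reaction id="inflow" reversible="false">\n'
        '        <listOfProducts><speciesReference species="S0" stoichiometry="1" constant="true"/></listOfProducts>\n'
        "        <kineticLaw><math xmlns=\"http://www.w3.org/1998/Math/MathML\"><ci> J_in </ci></math></kineticLaw>\n"
        "      </reaction>\n"
    )
    mm_law = (
        '        <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">\n'
        "          <apply><divide/>\n"
        "            <apply><times/><ci> {vmax} </ci><ci> {s} </ci></apply>\n"
        "            <apply><plus/><ci> {km} </ci><ci> {s} </ci></apply>\n"
        "          </apply>\n"
        "        </math></kineticLaw>\n"
    )
    for i in range(n):
        parts.append(
            f'      <reaction id="R{i+1}" reversible="false">\n'
            f'        <listOfReactants><speciesReference species="S{i}" stoichiometry="1" constant="true"/></listOfReactants>\n'
            f'        <listOfProducts><speciesReference species="S{i+1}" stoichiometry="1" constant="true"/></listOfProducts>\n'
            + mm_law.format(vmax=f"Vmax{i+1}", km=f"Km{i+1}", s=f"S{i}")
            + "      </reaction>\n"
        )
    parts.append(
        '      <reaction id="sink" reversible="false">\n'
        f'        <listOfReactants><speciesReference species="S{n}" stoichiometry="1" constant="true"/></listOfReactants>\n'
        '        <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">'
        f"<apply><times/><ci> k_out </ci><ci> S{n} </ci></apply></math></kineticLaw>\n"
        "      </reaction>\n"
    )
    parts.append("    </listOfReactions>\n  </model>\n</sbml>\n")
    Path(path).write_text("".join(parts), encoding="utf-8")
    return model, p_true
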