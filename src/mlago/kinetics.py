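"""Kinetic models, simulation, badness-of-fit, and quasi-experimental data.

A kinetic model is a system of ODEs dx/dt = f(t, x, p) over named
molecular concentrations x with named kinetic parameters p (Michaelis
constants flagged by ``km_mask``). Badness-of-fit (BOF) against a
concentration dataset is the root-mean-square *relative* error over all
available (condition, timepoint, molecule) cells, which makes it
invariant under joint rescaling of simulation and data.

Integration failures inside optimization loops are reported through a
large sentinel BOF rather than raised, so global optimizers can rank
infeasible parameter vectors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

logger = logging.getLogger(__name__)

#: BOF reported when the integrator fails or produces non-finite states
BOF_SENTINEL = 1e10
#: data cells with |value| below this floor are masked out of the BOF mean
DATA_FLOOR = 1e-9

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


@dataclass
class Condition:
    """One experimental condition: a named initial state, optional inputs."""

    name: str
    initial_state: np.ndarray
    inputs: dict = field(default_factory=dict)


@dataclass
class KineticModel:
    """ODE right-hand side with named states and parameters.

    ``rhs(t, x, p)`` returns dx/dt with ``len(state_names)`` entries.
    ``km_mask[i]`` is True where ``parameter_names[i]`` is a Michaelis
    constant; ``annotations`` maps K_m parameter names to
    (EC number, compound ID, organism ID) triples for predictor queries.
    """

    name: str
    state_names: list[str]
    parameter_names: list[str]
    km_mask: np.ndarray
    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    conditions: dict[str, Condition]
    annotations: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.km_mask = np.asarray(self.km_mask, dtype=bool)
        if len(self.km_mask) != len(self.parameter_names):
            raise ValueError("km_mask length must equal the number of parameters")

    @property
    def km_names(self) -> list[str]:
        return [n for n, m in zip(self.parameter_names, self.km_mask) if m]

    def parameter_index(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.parameter_names.index(n) for n in names], dtype=int)


@dataclass
class SimulationResult:
    timepoints: np.ndarray
    trajectory: np.ndarray  # (n_point, n_state)
    success: bool
    message: str = ""
    nfev: int = 0


@dataclass
class ExperimentalDataset:
    """Measured concentrations indexed by (condition, timepoint, molecule).

    ``values`` has shape (n_exp, n_point, n_mol); ``mask`` marks available
    cells. Cells whose value is below the floor are masked out so the
    relative-error mean in the BOF is always well defined; the mean runs
    over the masked-in cell count, which also supports ragged data.
    """

    conditions: list[str]
    timepoints: np.ndarray
    molecules: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = (len(self.conditions), len(self.timepoints), len(self.molecules))
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(f"values/mask must have shape {expected}")
        bad = self.mask & ~np.isfinite(self.values)
        if bad.any():
            raise ValueError("masked-in values must be finite")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def simulate(
    model: KineticModel,
    p: np.ndarray,
    condition: str,
    timepoints: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate one condition at the given timepoints.

    Uses a stiff-capable integrator (LSODA by default). Failure —
    non-convergence or non-finite states — is reported via
    ``result.success``, never raised, so optimizers can penalize it.
    Raises only for an unknown condition or non-increasing timepoints.
    """
    if condition not in model.conditions:
        raise KeyError(f"unknown condition {condition!r}; have {list(model.conditions)}")
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing and non-empty")
    x0 = np.asarray(model.conditions[condition].initial_state, dtype=float)
    p = np.asarray(p, dtype=float)
    t0 = min(0.0, t[0])
    if method == "LSODA":
        # fast Fortran path; prepend t0 so integration starts at the model's origin
        t_solve = np.concatenate([[t0], t]) if t[0] > t0 else t
        try:
            import warnings

            with warnings.catch_warnings():
                # failures are reported via the success flag, not warnings
                warnings.simplefilter("ignore")
                y, info = odeint(
                    model.rhs, x0, t_solve, args=(p,), tfirst=True,
                    rtol=rtol, atol=atol, full_output=True, printmessg=False,
                )
        except Exception as exc:  # blow-up inside the RHS
            return SimulationResult(t, np.full((len(t), len(x0)), np.nan), False, str(exc))
        traj = y[1:] if len(t_solve) > len(t) else y
        message = info["message"]
        ok = message == "Integration successful." and np.isfinite(traj).all()
        if not ok:
            traj = np.full((len(t), len(x0)), np.nan)
        return SimulationResult(t, traj, ok, message, int(info["nfe"][-1]))
    try:
        sol = solve_ivp(
            model.rhs, (t0, t[-1]), x0, t_eval=t, args=(p,),
            method=method, rtol=rtol, atol=atol,
        )
    except Exception as exc:  # stiff blow-up inside user RHS
        return SimulationResult(t, np.full((len(t), len(x0)), np.nan), False, str(exc))
    traj = sol.y.T if sol.success else np.full((len(t), len(x0)), np.nan)
    ok = bool(sol.success) and np.isfinite(traj).all()
    return SimulationResult(t, traj, ok, sol.message, int(sol.nfev))


def bof(sim_values: np.ndarray, data: ExperimentalDataset) -> float:
    """Root-mean-square relative error of aligned predictions vs data.

    ``sqrt(mean over masked-in cells of ((sim − exp) / exp)²)``. Zero iff
    the prediction matches the data on every available cell.
    """
    sim_values = np.asarray(sim_values, dtype=float)
    if sim_values.shape != data.values.shape:
        raise ValueError(f"sim shape {sim_values.shape} != data shape {data.values.shape}")
    m = data.mask
    if not m.any():
        raise ValueError("empty mask: no data cells available")
    exp = data.values[m]
    if np.any(np.abs(exp) < DATA_FLOOR):
        raise ValueError("masked-in data contain values below the floor; re-mask the dataset")
    rel = (sim_values[m] - exp) / exp
    return float(np.sqrt(np.mean(rel**2)))


def evaluate_bof(
    model: KineticModel,
    p: np.ndarray,
    data: ExperimentalDataset,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    sentinel: float = BOF_SENTINEL,
) -> float:
    """Simulate every condition at the dataset's timepoints and score the fit.

    Returns the sentinel (default 1e10) on any integration failure so the
    point still ranks, as maximally violating, inside optimization loops.
    """
    sims = np.empty_like(data.values)
    mol_idx = [model.state_names.index(mname) for mname in data.molecules]
    for i, cond in enumerate(data.conditions):
        res = simulate(model, p, cond, data.timepoints, rtol=rtol, atol=atol, method=method)
        if not res.success:
            logger.debug("evaluate_bof: integration failed in %r (%s)", cond, res.message)
            return sentinel
        sims[i] = res.trajectory[:, mol_idx]
    try:
        return bof(sims, data)
    except ValueError:
        return sentinel


def generate_quasi_data(
    model: KineticModel,
    p_true: np.ndarray,
    timepoints: Sequence[float],
    noise_cv: float = 0.0,
    seed: int | None = None,
    conditions: Sequence[str] | None = None,
    molecules: Sequence[str] | None = None,
    floor: float = DATA_FLOOR,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ExperimentalDataset:
    """Quasi-experimental data: simulate at reference parameters.

    With ``noise_cv = 0`` the data are the noiseless simulated
    trajectories (the round trip BOF(p_true) is then ~0). Positive
    ``noise_cv`` multiplies each cell by a median-1 lognormal factor with
    that coefficient of variation; at small CV the expected BOF at p_true
    approaches the CV. Cells below the floor are masked out (count
    logged). Raises on simulation failure at ``p_true``.
    """
    conds = list(conditions) if conditions is not None else list(model.conditions)
    mols = list(molecules) if molecules is not None else list(model.state_names)
    t = np.asarray(timepoints, dtype=float)
    mol_idx = [model.state_names.index(m) for m in mols]
    values = np.empty((len(conds), len(t), len(mols)))
    for i, cond in enumerate(conds):
        res = simulate(model, p_true, cond, t, rtol=rtol, atol=atol)
        if not res.success:
            raise RuntimeError(f"simulation failed at p_true in condition {cond!r}: {res.message}")
        values[i] = res.trajectory[:, mol_idx]
    mask = np.abs(values) >= floor
    n_masked_out = values.size - int(mask.sum())
    if n_masked_out:
        logger.info("generate_quasi_data: %d cells below floor masked out", n_masked_out)
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        values = values * np.exp(sigma * rng.standard_normal(values.shape))
    return ExperimentalDataset(conds, t, mols, values, mask)


# ---------------------------------------------------------------------------
# delimited-text I/O for experimental data (long format)


def write_dataset(data: ExperimentalDataset, path: str | Path, sep: str = "\t") -> None:
    """Long-format writer: columns condition, time, molecule, value."""
    rows = []
    for i, cond in enumerate(data.conditions):
        for j, t in enumerate(data.timepoints):
            for k, mol in enumerate(data.molecules):
                if data.mask[i, j, k]:
                    rows.append((cond, t, mol, data.values[i, j, k]))
    pd.DataFrame(rows, columns=["condition", "time", "molecule", "value"]).to_csv(
        path, sep=sep, index=False
    )


def read_dataset(path: str | Path, sep: str = "\t") -> ExperimentalDataset:
    """Read a long-format dataset; missing (condition, time, molecule) cells are masked out."""
    df = pd.read_csv(path, sep=sep)
    conds = list(pd.unique(df["condition"].astype(str)))
    times = np.array(sorted(df["time"].unique()), dtype=float)
    mols = list(pd.unique(df["molecule"].astype(str)))
    values = np.full((len(conds), len(times), len(mols)), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    t_index = {t: j for j, t in enumerate(times)}
    c_index = {c: i for i, c in enumerate(conds)}
    m_index = {m: k for k, m in enumerate(mols)}
    for row in df.itertuples(index=False):
        i, j, k = c_index[str(row.condition)], t_index[float(row.time)], m_index[str(row.molecule)]
        values[i, j, k] = float(row.value)
        mask[i, j, k] = True
    values = np.where(mask, values, 0.0)
    return ExperimentalDataset(conds, times, mols, values, mask)


# ---------------------------------------------------------------------------
# minimal SBML reader (L2/L3 core subset: reactions with kinetic laws)


class SbmlError(ValueError):
    """Malformed SBML input."""


class SbmlUnsupportedError(SbmlError):
    """Well-formed SBML using constructs outside the supported subset."""


_KM_NAME_RE = re.compile(r"(?i)(^|[_.])km")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_mathml(node):
    """Content MathML -> nested tuple AST ('op', args...) | ('ci', id) | ('cn', value)."""
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SbmlUnsupportedError("expected a single expression under <math>")
        return _parse_mathml(children[0])
    if tag == "ci":
        return ("ci", node.text.strip())
    if tag == "cn":
        cn_type = node.attrib.get("type", "real")
        if cn_type in ("real", "integer"):
            return ("cn", float(node.text.strip()))
        if cn_type == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return ("cn", float(parts[0]) * 10.0 ** float(parts[1]))
        raise SbmlUnsupportedError(f"unsupported <cn type='{cn_type}'>")
    if tag == "csymbol":
        url = node.attrib.get("definitionURL", "")
        if url.endswith("/time"):
            return ("time",)
        raise SbmlUnsupportedError(f"unsupported csymbol {url!r}")
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = [_parse_mathml(c) for c in children[1:]]
        if op in ("plus", "minus", "times", "divide", "power", "root", "exp", "ln", "log"):
            return (op, *args)
        raise SbmlUnsupportedError(f"unsupported MathML operator <{op}>")
    raise SbmlUnsupportedError(f"unsupported MathML element <{tag}>")


def _eval_ast(ast, env: Mapping[str, float], t: float) -> float:
    op = ast[0]
    if op == "ci":
        try:
            return env[ast[1]]
        except KeyError:
            raise SbmlError(f"unknown identifier {ast[1]!r} in kinetic law") from None
    if op == "cn":
        return ast[1]
    if op == "time":
        return t
    args = [_eval_ast(a, env, t) for a in ast[1:]]
    if op == "plus":
        return sum(args)
    if op == "minus":
        return -args[0] if len(args) == 1 else args[0] - args[1]
    if op == "times":
        out = 1.0
        for a in args:
            out *= a
        return out
    if op == "divide":
        return args[0] / args[1]
    if op == "power":
        return args[0] ** args[1]
    if op == "root":
        return args[-1] ** 0.5 if len(args) == 1 else args[-1] ** (1.0 / args[0])
    if op == "exp":
        return float(np.exp(args[0]))
    if op == "ln":
        return float(np.log(args[0]))
    if op == "log":
        return float(np.log10(args[-1]))
    raise SbmlUnsupportedError(f"unsupported operator {op!r}")


def load_sbml(
    path: str | Path,
    km_annotations: Mapping[str, tuple[str, str, str]] | None = None,
    condition_name: str = "default",
) -> KineticModel:
    """Load a kinetic model from an SBML file (L2/L3 core subset).

    Supported: compartments, species with initial concentrations,
    global and reaction-local parameters, reactions with content-MathML
    kinetic laws. Events, rules, function definitions, and delays raise
    :class:`SbmlUnsupportedError` naming the offending elements.

    Parameters named like K_m's (matching ``km``/``Km`` prefixes, e.g.
    ``Km1``, ``km_glc``, ``R1.Km``) are flagged in ``km_mask``; the
    optional ``km_annotations`` map (parameter name -> (EC, compound,
    organism)) both overrides the flag and attaches predictor queries.
    """
    from lxml import etree

    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SbmlError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlError(f"{path}: root element is <{_local(root.tag)}>, not <sbml>")
    model_el = next((c for c in root if _local(c.tag) == "model"), None)
    if model_el is None:
        raise SbmlError(f"{path}: no <model> element")

    def section(name):
        el = next((c for c in model_el if _local(c.tag) == name), None)
        return list(el) if el is not None else []

    unsupported = [
        f"{_local(c.tag)}"
        for c in model_el
        if _local(c.tag) in ("listOfEvents", "listOfRules", "listOfFunctionDefinitions", "listOfConstraints")
        and len(c)
    ]
    if unsupported:
        raise SbmlUnsupportedError(f"{path}: unsupported SBML constructs: {unsupported}")

    compartments = {
        c.attrib["id"]: float(c.attrib.get("size", c.attrib.get("volume", 1.0)))
        for c in section("listOfCompartments")
    }

    state_names: list[str] = []
    fixed_species: dict[str, float] = {}
    init_conc: list[float] = []
    for s in section("listOfSpecies"):
        sid = s.attrib["id"]
        conc = float(s.attrib.get("initialConcentration", s.attrib.get("initialAmount", 0.0)))
        boundary = s.attrib.get("boundaryCondition", "false") == "true"
        constant = s.attrib.get("constant", "false") == "true"
        if boundary or constant:
            fixed_species[sid] = conc
        else:
            state_names.append(sid)
            init_conc.append(conc)

    parameter_names: list[str] = []
    param_values: list[float] = []
    for prm in section("listOfParameters"):
        parameter_names.append(prm.attrib["id"])
        param_values.append(float(prm.attrib.get("value", np.nan)))

    reactions = []
    for rx in section("listOfReactions"):
        rid = rx.attrib["id"]
        reac, prod, math_ast = [], [], None
        for part in rx:
            pname = _local(part.tag)
            if pname in ("listOfReactants", "listOfProducts"):
                target = reac if pname == "listOfReactants" else prod
                for sr in part:
                    target.append((sr.attrib["species"], float(sr.attrib.get("stoichiometry", 1.0))))
            elif pname == "kineticLaw":
                for kchild in part:
                    kname = _local(kchild.tag)
                    if kname == "math":
                        math_ast = _parse_mathml(kchild)
                    elif kname in ("listOfParameters", "listOfLocalParameters"):
                        for lp in kchild:
                            parameter_names.append(f"{rid}.{lp.attrib['id']}")
                            param_values.append(float(lp.attrib.get("value", np.nan)))
        if math_ast is None:
            raise SbmlUnsupportedError(f"{path}: reaction {rid!r} has no kinetic law")
        reactions.append((rid, reac, prod, math_ast))

    km_annotations = dict(km_annotations or {})
    km_mask = np.array(
        [bool(_KM_NAME_RE.search(n.rsplit(".", 1)[-1])) or n in km_annotations for n in parameter_names],
        dtype=bool,
    )

    state_index = {n: i for i, n in enumerate(state_names)}
    n_state = len(state_names)
    # stoichiometry matrix and local-parameter scoping per reaction
    stoich = np.zeros((n_state, len(reactions)))
    for j, (rid, reac, prod, _) in enumerate(reactions):
        for sid, st in reac:
            if sid in state_index:
                stoich[state_index[sid], j] -= st
        for sid, st in prod:
            if sid in state_index:
                stoich[state_index[sid], j] += st

    base_env = dict(compartments)
    base_env.update(fixed_species)
    param_names_frozen = list(parameter_names)

    def rhs(t, x, p):
        env = dict(base_env)
        env.update(zip(state_names, x))
        # global params under their own id; local params under bare id, scoped per reaction below
        for name, val in zip(param_names_frozen, p):
            if "." not in name:
                env[name] = val
        v = np.empty(len(reactions))
        for j, (rid, _, _, ast) in enumerate(reactions):
            local_env = env
            locals_for_rx = {
                name.split(".", 1)[1]: val
                for name, val in zip(param_names_frozen, p)
                if name.startswith(rid + ".")
            }
            if locals_for_rx:
                local_env = {**env, **locals_for_rx}
            v[j] = _eval_ast(ast, local_env, t)
        return stoich @ v

    model = KineticModel(
        name=model_el.attrib.get("id", path.stem),
        state_names=state_names,
        parameter_names=parameter_names,
        km_mask=km_mask,
        rhs=rhs,
        conditions={condition_name: Condition(condition_name, np.array(init_conc, dtype=float))},
        annotations=km_annotations,
    )
    model.default_parameters = np.array(param_values, dtype=float)  # type: ignore[attr-defined]
    return model
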