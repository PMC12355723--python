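"""Run configuration, scheme drivers, and result serialization.

``run_scheme`` executes one multilevel calculation described by a
``RunConfig`` — projection-based embedding in any ansatz combination,
an ONIOM baseline, a vacuum-model calculation, or a plain supersystem
SCF — and returns the result together with a serializable report.
``error_vs_subsystem_curve`` assembles reaction energies over nested
active sets and their unsigned errors against a reference.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .adapter import FUNCTIONALS, XCFunctionalSpec, build_context
from .dispersion import S6_BY_FUNCTIONAL, dispersion_energy
from .molecule import ConfigurationError, MoleculeSpec, read_xyz

HARTREE_TO_KCAL = 627.509474

_SCHEMES = ("pbe", "oniom_me", "oniom_ee", "vacuum", "supersystem")
_ANSATZE = ("uks", "roks")


@dataclasses.dataclass
class MethodSpec:
    """One level of theory: functional, optional correlation/dispersion."""

    functional: str
    correlation: str = "none"       # none | mp2
    dispersion: bool = False

    def resolve(self) -> XCFunctionalSpec:
        return XCFunctionalSpec.resolve(self.functional)

    @property
    def s6(self) -> float:
        return S6_BY_FUNCTIONAL.get(self.functional.lower(), 1.0)


@dataclasses.dataclass
class RunConfig:
    """Complete description of one multilevel run."""

    molecule: MoleculeSpec
    basis: str
    scheme: str = "pbe"
    high: MethodSpec = dataclasses.field(
        default_factory=lambda: MethodSpec("pbe0"))
    low: MethodSpec = dataclasses.field(
        default_factory=lambda: MethodSpec("pbe"))
    ansatz_low: str = "uks"
    ansatz_high: str = "uks"
    active_atoms: tuple = ()
    border_pairs: tuple = ()
    partition_method: str = "spade"
    mulliken_threshold: float = 0.3
    charge_scheme: str = "iao"
    grid_level: int = 1
    output: str = None

    def __post_init__(self):
        if self.scheme not in _SCHEMES:
            raise ConfigurationError(
                f"unknown scheme {self.scheme!r} (have {_SCHEMES})")
        if self.ansatz_low not in _ANSATZE or self.ansatz_high not in _ANSATZE:
            raise ConfigurationError("ansatz must be 'uks' or 'roks'")
        for m in (self.high, self.low):
            if m.functional.lower() not in FUNCTIONALS:
                raise ConfigurationError(
                    f"unknown functional {m.functional!r}")
            if m.correlation not in ("none", "mp2"):
                raise ConfigurationError(
                    f"unknown correlation method {m.correlation!r}")
        if self.high.correlation == "mp2" and \
                self.high.functional.lower() != "hf":
            raise ConfigurationError(
                "MP2 correlation requires an HF high-level reference")
        if self.scheme != "supersystem" and not self.active_atoms:
            raise ConfigurationError(
                f"scheme {self.scheme!r} needs a nonempty active_atoms list")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "xyz" in d:
            mol = read_xyz(d.pop("xyz"), d.pop("charge", 0),
                           d.pop("multiplicity", 1))
        elif "fixture" in d:
            from .fixtures import get_fixture
            mol = get_fixture(d.pop("fixture"),
                              **d.pop("fixture_args", {}))
        else:
            mol = MoleculeSpec.from_lists(
                [a[0] for a in d["atoms"]],
                [list(a[1:]) for a in d["atoms"]],
                d.pop("charge", 0), d.pop("multiplicity", 1))
            d.pop("atoms")
        for key in ("high", "low"):
            if key in d and isinstance(d[key], dict):
                d[key] = MethodSpec(**d[key])
            elif key in d and isinstance(d[key], str):
                d[key] = MethodSpec(d[key])
        d["active_atoms"] = tuple(d.get("active_atoms", ()))
        d["border_pairs"] = tuple(tuple(p) for p in d.get("border_pairs", ()))
        return cls(molecule=mol, **d)


def _virtuals_outside_env(C, occ_idx, R_env, S, guard=0.5):
    """Columns of C that are neither occupied nor environment-spanned."""
    n = C.shape[1]
    if R_env is None or not np.any(R_env):
        return np.asarray([i for i in range(n) if i not in set(occ_idx)])
    ov = np.einsum("mi,mn,np,pq,qi->i", C, S, R_env, S, C, optimize=True)
    return np.asarray([i for i in range(n)
                       if i not in set(occ_idx) and ov[i] <= guard])


def _embedded_mp2(result, ctx, xc_high, ansatz_high: str) -> float:
    """MP2 of the embedded subsystem: active occupieds, full virtual space
    (environment-occupied directions excluded), embedded Fock."""
    from .mp2 import ump2_energy
    from .uks import SpinDensities, build_uks_fock
    S = ctx.S
    if ansatz_high == "uks":
        Ca, Cb = result.C
        pa = result.extras["partition_alpha"]
        pb = result.extras["partition_beta"]
        pot = result.extras["potential"]
        na, nb = pa.n_active, pb.n_active
        Fa, Fb = build_uks_fock(result.densities, ctx, xc_high)
        Fa, Fb = Fa + pot.V_alpha, Fb + pot.V_beta
        va = _virtuals_outside_env(Ca, range(na), pa.R_env, S)
        vb = _virtuals_outside_env(Cb, range(nb), pb.R_env, S)
        return ump2_energy(ctx, (Ca[:, :na], Cb[:, :nb]),
                           (Ca[:, va], Cb[:, vb]), (Fa, Fb))
    # restricted open-shell path: shared orbitals, per-spin embedded Focks
    C = result.C
    pot = result.extras["potential"]
    part = result.extras["partition"]
    nc = result.extras["n_closed_A"]
    no = result.extras["ensemble"].n_open
    d = result.densities
    Fa, Fb = build_uks_fock(SpinDensities(d.D_alpha, d.D_beta, "A"),
                            ctx, xc_high)
    core = pot.h_core_AinB - ctx.h_core
    dVa = pot.Vxc_emb_o
    dVb = 2.0 * pot.Vxc_emb_c - pot.Vxc_emb_o
    Fa, Fb = Fa + core + dVa, Fb + core + dVb
    na, nb = nc + no, nc
    vir = _virtuals_outside_env(C, range(na), part.R_env, S)
    vir_b = _virtuals_outside_env(C, range(nb), part.R_env, S)
    return ump2_energy(ctx, (C[:, :na], C[:, :nb]),
                       (C[:, vir], C[:, vir_b]), (Fa, Fb))


def _pbe_dispersion(config: RunConfig) -> float:
    """Subsystem-resolved pairwise dispersion for the multilevel energy."""
    if not (config.high.dispersion or config.low.dispersion):
        return 0.0
    mol, act = config.molecule, config.active_atoms
    e = 0.0
    if config.low.dispersion:
        e += dispersion_energy(mol, None, config.low.s6)
        e -= dispersion_energy(mol, act, config.low.s6)
    if config.high.dispersion:
        e += dispersion_energy(mol, act, config.high.s6)
    return e


def run_scheme(config: RunConfig, log=None):
    """Execute one configured calculation; returns (result, report dict)."""
    mol = config.molecule
    xc_low = config.low.resolve()
    xc_high = config.high.resolve()
    if config.scheme == "supersystem":
        from .ro import solve_ro
        from .uks import solve_uks
        ctx = build_context(mol, config.basis, config.grid_level)
        if config.ansatz_high == "roks":
            r = solve_ro(mol, ctx, xc_high)
        else:
            r = solve_uks(mol, ctx, xc_high)
        e = r.energy
        e_cor = 0.0
        if config.high.correlation == "mp2":
            from .mp2 import mp2_ro, mp2_rhf, ump2_energy
            from .uks import SpinDensities, build_uks_fock
            if config.ansatz_high == "roks":
                d = r.densities
                Fa, Fb = build_uks_fock(
                    SpinDensities(d.D_alpha, d.D_beta), ctx, xc_high)
                e_cor = mp2_ro(ctx, r.C, r.n_closed, r.n_open, Fa, Fb)
            else:
                Fa, Fb = build_uks_fock(r.densities, ctx, xc_high)
                e_cor = ump2_energy(
                    ctx, (r.C_alpha[:, :r.n_alpha], r.C_beta[:, :r.n_beta]),
                    (r.C_alpha[:, r.n_alpha:], r.C_beta[:, r.n_beta:]),
                    (Fa, Fb))
        e_disp = dispersion_energy(mol, None, config.high.s6) \
            if config.high.dispersion else 0.0
        report = {"scheme": "supersystem", "E_scf": e, "E_cor": e_cor,
                  "E_disp": e_disp, "E_total": e + e_cor + e_disp}
        _finish(report, config, log)
        return r, report
    if config.scheme in ("oniom_me", "oniom_ee", "vacuum"):
        from .baselines import (cap_with_link_atoms, oniom_ee, oniom_me,
                                vacuum_embedding_energy)
        ms = cap_with_link_atoms(mol, config.active_atoms,
                                 config.border_pairs)
        if config.scheme == "vacuum":
            e = vacuum_embedding_energy(ms, xc_high, config.basis,
                                        config.grid_level,
                                        config.ansatz_high)
        elif config.scheme == "oniom_me":
            e = oniom_me(ms, xc_high, xc_low, config.basis,
                         config.grid_level, config.ansatz_high)
        else:
            e = oniom_ee(ms, xc_high, xc_low, config.basis,
                         config.grid_level, config.ansatz_high,
                         config.charge_scheme)
        e_disp = 0.0
        if config.high.dispersion or config.low.dispersion:
            if config.low.dispersion and config.scheme != "vacuum":
                e_disp += dispersion_energy(mol, None, config.low.s6)
                e_disp -= dispersion_energy(ms.model, None, config.low.s6)
            if config.high.dispersion:
                e_disp += dispersion_energy(ms.model, None, config.high.s6)
        report = {"scheme": config.scheme, "E_scf": e, "E_disp": e_disp,
                  "E_total": e + e_disp,
                  "model_atoms": list(ms.model.symbols)}
        _finish(report, config, log)
        return ms, report
    # projection-based embedding
    from .combine import roks_in_uks, uks_in_roks
    from .embed_roks import run_roks_embedding
    from .embed_uks import run_uks_embedding
    ctx = build_context(mol, config.basis, config.grid_level)
    pair = (config.ansatz_low, config.ansatz_high)
    kw = dict(partition_method=config.partition_method,
              mulliken_threshold=config.mulliken_threshold, log=log)
    if pair == ("uks", "uks"):
        res = run_uks_embedding(mol, ctx, xc_low, xc_high,
                                config.active_atoms, **kw)
    elif pair == ("roks", "roks"):
        res = run_roks_embedding(mol, ctx, xc_low, xc_high,
                                 config.active_atoms, **kw)
    elif pair == ("roks", "uks"):
        res = uks_in_roks(mol, ctx, xc_low, xc_high, config.active_atoms,
                          **kw)
    else:
        res = roks_in_uks(mol, ctx, xc_low, xc_high, config.active_atoms,
                          **kw)
    if config.high.correlation == "mp2":
        res.E_cor = _embedded_mp2(res, ctx, xc_high, config.ansatz_high)
    res.E_disp = _pbe_dispersion(config)
    report = {
        "scheme": "pbe",
        "ansatz": f"{config.ansatz_high}-in-{config.ansatz_low}",
        "E_low_AB": res.E_low_AB,
        "E_low_A": res.E_low_A,
        "E_high_A": res.E_high_A,
        "V_nn": res.V_nn,
        "correction": res.correction,
        "E_pbe": res.E_pbe,
        "E_cor": res.E_cor,
        "E_disp": res.E_disp,
        "E_total": res.E_total,
        "orthogonality_residual": res.orthogonality_residual,
        "s_squared": res.s_squared,
        "n_iter": res.n_iter,
    }
    _finish(report, config, log)
    return res, report


def _finish(report: dict, config: RunConfig, log):
    report["basis"] = config.basis
    report["high"] = dataclasses.asdict(config.high)
    report["low"] = dataclasses.asdict(config.low)
    if log is not None:
        for k, v in report.items():
            log(f"{k:26s} {v}")
    if config.output:
        save_report(report, config.output)


def save_report(report: dict, path: str):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
        fh.write("\n")


def load_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def reaction_energy(species) -> float:
    """Sum of coefficient * E_total over (coefficient, RunConfig) pairs."""
    total = 0.0
    for coeff, cfg in species:
        _, rep = run_scheme(cfg)
        total += coeff * rep["E_total"]
    return total


def error_vs_subsystem_curve(levels, reference_hartree: float):
    """Reaction-energy errors across nested active-set levels.

    ``levels`` is a list of {"label": str, "species": [(coeff, RunConfig),
    ...]}; the return value is one row per level with the reaction energy
    and its unsigned error versus ``reference_hartree`` in kcal/mol.
    Failures are recorded as missing cells rather than raised.
    """
    rows = []
    for level in levels:
        row = {"label": level["label"]}
        try:
            de = reaction_energy(level["species"])
            row["reaction_kcal"] = de * HARTREE_TO_KCAL
            row["error_kcal"] = abs(de - reference_hartree) * HARTREE_TO_KCAL
        except Exception as exc:          # recorded, not fatal
            row["reaction_kcal"] = None
            row["error_kcal"] = None
            row["failure"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return rows
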