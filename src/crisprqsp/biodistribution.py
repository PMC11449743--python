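"""Whole-body disposition model for LNP, sgRNA, mRNA, Cas9 and RNP.

State layout (amounts in ug unless noted): plasma and liver-vascular pools
for free/opsonized LNP, sgRNA and mRNA; an MPS pool; liver-interstitial
free LNP, receptor-bound LNP complex, sgRNA and mRNA; liver-cellular sgRNA,
mRNA, Cas9 and RNP; free LDL receptor (ug/mL, concentration state); kidney
pools for LNP and sgRNA only (the mRNA sub-model has no kidney compartment);
and a lumped remainder per analyte.

Kinetic processes: reversible opsonization (k_ass/k_dis), irreversible MPS
phagocytosis (k_int) with degradation (k_deg_LNP), lumped
endocytosis/exocytosis transfer (k_in_endo/k_out_exo) plus single-pore
convective lymph transport gated by reflection coefficients, LDL-receptor
binding (k_on_LNP/k_off_LNP, free fraction fu_LNP) with receptor turnover
(k_syn = LDL_tot*k_el), complex elimination (k_deg_DR) delivering carried
cargo to the cell, interstitial cargo release (k_release), translation
(k_trans), ribonucleoprotein assembly (k_on_RNP = k_off_RNP/KD), first-order
exonuclease degradation of the RNAs, and flow-limited renal filtration of
free LNP and sgRNA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from crisprqsp.dosing import DoseRegimen
from crisprqsp.physiology import SpeciesPhysiology, lymph_flow

ANALYTES = ("LNP", "sgRNA", "mRNA")

#: Kidney compartments exist for LNP and sgRNA, never for mRNA.
KIDNEY_ANALYTES = ("LNP", "sgRNA")

STATE_NAMES = (
    "pl_LNP_free",
    "pl_LNP_ops",
    "pl_sgRNA",
    "pl_mRNA",
    "lv_LNP_free",
    "lv_LNP_ops",
    "lv_sgRNA",
    "lv_mRNA",
    "mps_LNP",
    "li_LNP_free",
    "li_LNP_complex",
    "li_sgRNA",
    "li_mRNA",
    "lc_sgRNA",
    "lc_mRNA",
    "lc_Cas9",
    "lc_RNP",
    "R_free",  # ug/mL
    "kid_LNP",
    "kid_sgRNA",
    "rem_LNP",
    "rem_sgRNA",
    "rem_mRNA",
)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_PK_STATES = len(STATE_NAMES)


@dataclass(frozen=True)
class PKParameters:
    """Drug-specific rate constants (units as annotated per field).

    Derived quantities are recomputed, never stored: the receptor synthesis
    rate ``k_syn = LDL_tot * k_el`` (ug/mL/h) and the RNP association
    constant ``k_on_RNP = k_off_RNP / KD_mass`` with KD converted from nM to
    ug/mL through the Cas9 molecular weight.
    """

    k_in_endo: float  # 1/h, lumped endocytosis (LNP, sgRNA, mRNA)
    k_out_exo: float  # 1/h, lumped exocytosis
    k_deg_DR: float  # 1/h, degradation of the LNP-receptor complex
    LDL_tot: float  # ug/mL, total LDL receptor concentration
    k_dis: float  # 1/h, dissociation from opsonins
    k_ass: float  # 1/h, association to opsonins
    k_release: float  # 1/h, cargo release from interstitial free LNP
    k_deg_LNP: float  # 1/h, degradation of unbound LNP
    k_el: float  # 1/h, elimination of the LDL receptor
    k_deg_sgRNA: float  # 1/h
    k_deg_mRNA: float  # 1/h
    k_off_RNP: float  # 1/h
    KD: float  # nM, RNP equilibrium dissociation constant
    k_int: float  # 1/h, MPS phagocytosis
    k_on_LNP: float  # per (ug/mL) per h
    k_off_LNP: float  # 1/h
    fu_LNP: float  # plasma free fraction of LNP
    fu_RNA: float  # plasma free fraction of sgRNA / mRNA
    k_trans: float  # 1/h, mRNA -> Cas9 translation
    k_deg_Cas: float | None = None  # 1/h; defaults to k_deg_mRNA when None
    MW_Cas9: float = 160_000.0  # g/mol, for the nM -> ug/mL conversion

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        for name in ("fu_LNP", "fu_RNA"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.KD <= 0 or self.MW_Cas9 <= 0:
            raise ValueError("KD and MW_Cas9 must be strictly positive")

    @property
    def k_syn(self) -> float:
        """Receptor synthesis rate, ug/mL/h (= LDL_tot * k_el by construction)."""
        return self.LDL_tot * self.k_el

    @property
    def KD_mass(self) -> float:
        """KD converted from nM to ug/mL via MW_Cas9."""
        return self.KD * self.MW_Cas9 * 1e-6

    @property
    def k_on_RNP(self) -> float:
        """RNP association constant, per (ug/mL) per h (= k_off_RNP / KD_mass)."""
        return self.k_off_RNP / self.KD_mass

    @property
    def k_deg_Cas_eff(self) -> float:
        return self.k_deg_mRNA if self.k_deg_Cas is None else self.k_deg_Cas

    def replace(self, **kwargs) -> "PKParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ModelTopology:
    """Which analytes are present and whether each has a kidney compartment."""

    analytes: tuple[str, ...] = ANALYTES
    kidney_analytes: tuple[str, ...] = KIDNEY_ANALYTES

    def __post_init__(self) -> None:
        for a in self.analytes:
            if a not in ANALYTES:
                raise ValueError(f"unknown analyte {a!r}")
        for a in self.kidney_analytes:
            if a == "mRNA":
                raise ValueError("mRNA has no kidney compartment (no renal elimination)")
            if a not in self.analytes:
                raise ValueError(f"kidney requested for absent analyte {a!r}")


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches not forced by the model narrative (documented defaults).

    ``cargo_to_cell_fraction``: fraction of receptor-internalized LNP cargo
    delivered to the cellular layer on complex degradation.
    ``sigma_V_RNA``: vascular reflection coefficient used for sgRNA/mRNA
    (defaults below the LNP value because of the size difference).
    ``renal_clearance_on``: disable to study a closed system.
    ``opsonize_in_plasma``: opsonin exchange runs in plasma as well as the
    liver vascular space.
    ``cell_exocytosis``: when True the lumped exocytosis constant also
    drains the cellular RNA pools; the default one-way cellular uptake
    (pinocytosis in, degradation only out) is required for the cellular RNP
    signal to reach a magnitude comparable to the fitted IC50 values.
    """

    cargo_to_cell_fraction: float = 1.0
    sigma_V_RNA: float = 0.90
    renal_clearance_on: bool = True
    opsonize_in_plasma: bool = True
    cell_exocytosis: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.cargo_to_cell_fraction <= 1.0:
            raise ValueError("cargo_to_cell_fraction must lie in [0, 1]")
        if not 0.0 <= self.sigma_V_RNA <= 1.0:
            raise ValueError("sigma_V_RNA must lie in [0, 1]")


# ----------------------------------------------------------------------
# Elemental flux operations (unit-testable against closed forms)
# ----------------------------------------------------------------------

def opsonin_flux(C_free: float, C_bound: float, k_ass: float, k_dis: float) -> tuple[float, float]:
    """Reversible opsonin binding: returns (d_free, d_bound); mass-conserving."""
    if C_free < 0 or C_bound < 0:
        raise ValueError("opsonin_flux: negative input")
    d_bound = k_ass * C_free - k_dis * C_bound
    return -d_bound, d_bound


def mps_flux(C_vasc_LNP: float, A_mps: float, k_int: float, k_deg_LNP: float) -> tuple[float, float]:
    """Irreversible MPS phagocytosis: returns (uptake, degradation) rates."""
    if C_vasc_LNP < 0 or A_mps < 0:
        raise ValueError("mps_flux: negative input")
    return k_int * C_vasc_LNP, k_deg_LNP * A_mps


def receptor_flux(
    C_LNP_int: float,
    R_free: float,
    C_complex: float,
    p: PKParameters,
) -> tuple[float, float, float]:
    """Receptor binding at the interstitial interface (concentration basis).

    Returns (binding, unbinding, dR_turnover): binding =
    k_on_LNP*fu_LNP*C*R, unbinding = k_off_LNP*C_complex, and the receptor
    synthesis/elimination turnover k_syn - k_el*R.  The caller combines
    these into amount- and concentration-state derivatives.
    """
    if C_LNP_int < 0 or R_free < 0 or C_complex < 0:
        raise ValueError("receptor_flux: negative input")
    binding = p.k_on_LNP * p.fu_LNP * C_LNP_int * R_free
    unbinding = p.k_off_LNP * C_complex
    turnover = p.k_syn - p.k_el * R_free
    return binding, unbinding, turnover


def transfer_flux(
    C_upper: float,
    C_lower: float,
    V_upper: float,
    V_lower: float,
    k_in_endo: float,
    k_out_exo: float,
    L: float,
    sigma: float,
) -> tuple[float, float]:
    """Lumped endocytic/convective exchange across one interface (ug/h).

    inward = k_in_endo*V_upper*C_upper + L*(1-sigma)*C_upper;
    outward = k_out_exo*V_lower*C_lower.
    """
    if V_upper <= 0 or V_lower <= 0:
        raise ValueError("transfer_flux: non-positive volume")
    inward = k_in_endo * V_upper * C_upper + L * (1.0 - sigma) * C_upper
    outward = k_out_exo * V_lower * C_lower
    return inward, outward


def intracellular_rhs(
    cell_state: np.ndarray,
    p: PKParameters,
    V_cell: float,
) -> np.ndarray:
    """Derivatives for the cellular (sgRNA, mRNA, Cas9, RNP) amounts.

    sgRNA drives RNP assembly as a concentration in the cellular volume and
    is not itself consumed (the driving-signal reading; its mass is small
    relative to Cas9).  RNP is tracked in Cas9-mass equivalents and does not
    degrade.
    """
    sg, m, cas, rnp = cell_state
    if min(sg, m, cas, rnp) < -1e-9:
        raise ValueError("intracellular_rhs: negative amounts")
    assembly = p.k_on_RNP * max(sg, 0.0) / V_cell * max(cas, 0.0)
    d_sg = -p.k_deg_sgRNA * sg
    d_m = -p.k_deg_mRNA * m
    d_cas = p.k_trans * m - assembly + p.k_off_RNP * rnp - p.k_deg_Cas_eff * cas
    d_rnp = assembly - p.k_off_RNP * rnp
    return np.array([d_sg, d_m, d_cas, d_rnp])


# ----------------------------------------------------------------------
# Assembled model
# ----------------------------------------------------------------------

@dataclass
class PKModel:
    """Assembled ODE right-hand side with its physiology, parameters and topology."""

    phys: SpeciesPhysiology
    params: PKParameters
    topology: ModelTopology = field(default_factory=ModelTopology)
    options: ModelOptions = field(default_factory=ModelOptions)

    @property
    def n_states(self) -> int:
        return N_PK_STATES

    def initial_state(self, regimen: DoseRegimen) -> np.ndarray:
        """Initial condition: bolus doses placed in plasma; receptor at LDL_tot."""
        y0 = np.zeros(N_PK_STATES)
        y0[IDX["R_free"]] = self.params.LDL_tot
        if regimen.route == "bolus":
            y0[IDX["pl_LNP_free"]] = regimen.amount_LNP
            y0[IDX["pl_sgRNA"]] = regimen.amount_sgRNA
            y0[IDX["pl_mRNA"]] = regimen.amount_mRNA
        return y0

    def rhs_reference(self, t: float, y: np.ndarray, regimen: DoseRegimen | None = None) -> np.ndarray:
        """Readable flux-by-flux state derivative (ug/h; receptor in ug/mL/h).

        This is the specification of the dynamics in terms of the elemental
        flux operations; :meth:`rhs` is an algebraically identical fast path
        (linear part cached as a matrix) checked against this one in tests.
        """
        if y.shape[-1] != N_PK_STATES:
            raise ValueError(f"state dimension {y.shape[-1]} != {N_PK_STATES}")
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at t={t}")
        p = self.params
        ph = self.phys
        opt = self.options

        Vpl, Vlv, Vli, Vlc = ph.V_plasma, ph.V_liver_vasc, ph.V_liver_int, ph.V_liver_cell
        Vk, Vr = ph.V_kidney, ph.V_remainder
        Qli, Qk, Qr = ph.Q_liver, ph.Q_kidney, ph.Q_remainder
        Lli, Lk, Lr = lymph_flow(ph, "liver"), lymph_flow(ph, "kidney"), lymph_flow(ph, "remainder")
        sV_LNP, sV_RNA, sI = ph.sigma_V, opt.sigma_V_RNA, ph.sigma_I

        d = np.zeros(N_PK_STATES)
        # solver steps can undershoot zero by ~atol; rate laws are evaluated
        # on the clipped state (pairwise transfers stay mass-conserving)
        a = np.maximum(y, 0.0)

        def A(name: str) -> float:
            return a[IDX[name]]

        def add(name: str, v: float) -> None:
            d[IDX[name]] += v

        # --- plasma <-> organ flow transport (venous return = Q - L) ----
        def organ_exchange(pl: str, org: str, Q: float, L: float, V_org: float, sV: float) -> None:
            inflow = Q * A(pl) / Vpl
            outflow = ((Q - L) + L * (1.0 - sV)) * A(org) / V_org
            add(pl, -inflow + outflow)
            add(org, inflow - outflow)

        # LNP free: liver vascular, kidney, remainder
        def liver_vasc_exchange(pl: str, lv: str) -> None:
            inflow = Qli * A(pl) / Vpl
            outflow = (Qli - Lli) * A(lv) / Vlv
            add(pl, -inflow + outflow)
            add(lv, inflow - outflow)

        liver_vasc_exchange("pl_LNP_free", "lv_LNP_free")
        liver_vasc_exchange("pl_LNP_ops", "lv_LNP_ops")
        liver_vasc_exchange("pl_sgRNA", "lv_sgRNA")
        liver_vasc_exchange("pl_mRNA", "lv_mRNA")

        organ_exchange("pl_LNP_free", "kid_LNP", Qk, Lk, Vk, sV_LNP)
        organ_exchange("pl_sgRNA", "kid_sgRNA", Qk, Lk, Vk, sV_RNA)
        organ_exchange("pl_LNP_free", "rem_LNP", Qr, Lr, Vr, sV_LNP)
        organ_exchange("pl_sgRNA", "rem_sgRNA", Qr, Lr, Vr, sV_RNA)
        organ_exchange("pl_mRNA", "rem_mRNA", Qr, Lr, Vr, sV_RNA)

        # --- opsonization (plasma optional, liver vascular always) ------
        if opt.opsonize_in_plasma:
            d_free, d_bound = opsonin_flux(A("pl_LNP_free"), A("pl_LNP_ops"), p.k_ass, p.k_dis)
            add("pl_LNP_free", d_free)
            add("pl_LNP_ops", d_bound)
        d_free, d_bound = opsonin_flux(A("lv_LNP_free"), A("lv_LNP_ops"), p.k_ass, p.k_dis)
        add("lv_LNP_free", d_free)
        add("lv_LNP_ops", d_bound)

        # --- MPS phagocytosis of vascular free LNP ----------------------
        uptake, degradation = mps_flux(max(A("lv_LNP_free"), 0.0), max(A("mps_LNP"), 0.0), p.k_int, p.k_deg_LNP)
        add("lv_LNP_free", -uptake)
        add("mps_LNP", uptake - degradation)

        # --- vascular -> interstitial transfer --------------------------
        def vasc_int_transfer(lv: str, li: str, sV: float, fu: float) -> None:
            inward, outward = transfer_flux(
                A(lv) / Vlv, A(li) / Vli, Vlv, Vli, p.k_in_endo, p.k_out_exo, Lli, sV
            )
            add(lv, -fu * inward + outward)
            add(li, fu * inward - outward)

        vasc_int_transfer("lv_LNP_free", "li_LNP_free", sV_LNP, 1.0)
        vasc_int_transfer("lv_sgRNA", "li_sgRNA", sV_RNA, p.fu_RNA)
        vasc_int_transfer("lv_mRNA", "li_mRNA", sV_RNA, p.fu_RNA)

        # --- lymph return: interstitial -> plasma at L*(1-sigma_I) ------
        for li_name, pl_name in (
            ("li_LNP_free", "pl_LNP_free"),
            ("li_sgRNA", "pl_sgRNA"),
            ("li_mRNA", "pl_mRNA"),
        ):
            flux = Lli * (1.0 - sI) * A(li_name) / Vli
            add(li_name, -flux)
            add(pl_name, flux)

        # --- interstitial -> cellular transfer (no convective term) -----
        k_out_cell = p.k_out_exo if opt.cell_exocytosis else 0.0
        for li_name, lc_name in (("li_sgRNA", "lc_sgRNA"), ("li_mRNA", "lc_mRNA")):
            inward, outward = transfer_flux(
                A(li_name) / Vli, A(lc_name) / Vlc, Vli, Vlc, p.k_in_endo, k_out_cell, 0.0, 0.0
            )
            add(li_name, -inward + outward)
            add(lc_name, inward - outward)

        # --- receptor binding of interstitial free LNP ------------------
        binding_c, unbinding_c, turnover = receptor_flux(
            max(A("li_LNP_free"), 0.0) / Vli, max(A("R_free"), 0.0), max(A("li_LNP_complex"), 0.0) / Vli, p
        )
        add("li_LNP_free", -binding_c * Vli + unbinding_c * Vli)
        add("li_LNP_complex", binding_c * Vli - unbinding_c * Vli)
        add("R_free", turnover - binding_c + unbinding_c)

        # --- complex elimination delivers carried cargo to the cell -----
        complex_loss = p.k_deg_DR * A("li_LNP_complex")
        add("li_LNP_complex", -complex_loss)
        if regimen is not None and regimen.lnp_ratio > 0:
            cargo = opt.cargo_to_cell_fraction * complex_loss / regimen.lnp_ratio
            add("lc_sgRNA", cargo * regimen.frac_sgRNA)
            add("lc_mRNA", cargo * regimen.frac_mRNA)

        # --- cargo release from interstitial free LNP -------------------
        release = p.k_release * A("li_LNP_free")
        add("li_LNP_free", -release)
        if regimen is not None and regimen.lnp_ratio > 0:
            released = release / regimen.lnp_ratio
            add("li_sgRNA", released * regimen.frac_sgRNA)
            add("li_mRNA", released * regimen.frac_mRNA)

        # --- free LNP degradation ---------------------------------------
        for name in ("pl_LNP_free", "lv_LNP_free", "li_LNP_free", "kid_LNP", "rem_LNP"):
            add(name, -p.k_deg_LNP * A(name))

        # --- RNA degradation --------------------------------------------
        for name in ("pl_sgRNA", "lv_sgRNA", "li_sgRNA", "kid_sgRNA", "rem_sgRNA"):
            add(name, -p.k_deg_sgRNA * A(name))
        for name in ("pl_mRNA", "lv_mRNA", "li_mRNA", "rem_mRNA"):
            add(name, -p.k_deg_mRNA * A(name))

        # --- intracellular translation / RNP assembly -------------------
        # cellular RNA degradation lives inside intracellular_rhs; the organ
        # loops above deliberately exclude the lc_* pools
        cell = np.array([A("lc_sgRNA"), A("lc_mRNA"), A("lc_Cas9"), A("lc_RNP")])
        d_cell = intracellular_rhs(np.maximum(cell, 0.0), p, Vlc)
        add("lc_sgRNA", d_cell[0])
        add("lc_mRNA", d_cell[1])
        add("lc_Cas9", d_cell[2])
        add("lc_RNP", d_cell[3])

        # --- renal elimination (flow-limited filtration surrogate) ------
        if opt.renal_clearance_on:
            add("kid_LNP", -p.fu_LNP * Qk * A("kid_LNP") / Vk)
            add("kid_sgRNA", -p.fu_RNA * Qk * A("kid_sgRNA") / Vk)

        # --- infusion input ----------------------------------------------
        if regimen is not None and regimen.route == "infusion":
            if 0.0 <= t < regimen.infusion_duration:
                dur = regimen.infusion_duration
                add("pl_LNP_free", regimen.amount_LNP / dur)
                add("pl_sgRNA", regimen.amount_sgRNA / dur)
                add("pl_mRNA", regimen.amount_mRNA / dur)

        return d

    # --- fast path ----------------------------------------------------
    def _linear_system(self, regimen: DoseRegimen | None):
        """Cached (M, c): constant linear operator and constant source."""
        key = (
            None
            if regimen is None
            else (regimen.frac_sgRNA, regimen.frac_mRNA, regimen.lnp_ratio)
        )
        cached = getattr(self, "_linsys_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1], cached[2]

        p, ph, opt = self.params, self.phys, self.options
        Vpl, Vlv, Vli, Vlc = ph.V_plasma, ph.V_liver_vasc, ph.V_liver_int, ph.V_liver_cell
        Vk, Vr = ph.V_kidney, ph.V_remainder
        Qli, Qk, Qr = ph.Q_liver, ph.Q_kidney, ph.Q_remainder
        Lli, Lk, Lr = lymph_flow(ph, "liver"), lymph_flow(ph, "kidney"), lymph_flow(ph, "remainder")
        sV_LNP, sV_RNA, sI = ph.sigma_V, opt.sigma_V_RNA, ph.sigma_I
        I = IDX

        M = np.zeros((N_PK_STATES, N_PK_STATES))
        c = np.zeros(N_PK_STATES)

        def liver_vasc(pl, lv):
            kin = Qli / Vpl
            kout = (Qli - Lli) / Vlv
            M[I[lv], I[pl]] += kin
            M[I[pl], I[pl]] -= kin
            M[I[pl], I[lv]] += kout
            M[I[lv], I[lv]] -= kout

        for pl, lv in (
            ("pl_LNP_free", "lv_LNP_free"),
            ("pl_LNP_ops", "lv_LNP_ops"),
            ("pl_sgRNA", "lv_sgRNA"),
            ("pl_mRNA", "lv_mRNA"),
        ):
            liver_vasc(pl, lv)

        def organ(pl, org, Q, L, V, sV):
            kin = Q / Vpl
            kout = ((Q - L) + L * (1.0 - sV)) / V
            M[I[org], I[pl]] += kin
            M[I[pl], I[pl]] -= kin
            M[I[pl], I[org]] += kout
            M[I[org], I[org]] -= kout

        organ("pl_LNP_free", "kid_LNP", Qk, Lk, Vk, sV_LNP)
        organ("pl_sgRNA", "kid_sgRNA", Qk, Lk, Vk, sV_RNA)
        organ("pl_LNP_free", "rem_LNP", Qr, Lr, Vr, sV_LNP)
        organ("pl_sgRNA", "rem_sgRNA", Qr, Lr, Vr, sV_RNA)
        organ("pl_mRNA", "rem_mRNA", Qr, Lr, Vr, sV_RNA)

        def opson(free, ops):
            M[I[ops], I[free]] += p.k_ass
            M[I[free], I[free]] -= p.k_ass
            M[I[free], I[ops]] += p.k_dis
            M[I[ops], I[ops]] -= p.k_dis

        if opt.opsonize_in_plasma:
            opson("pl_LNP_free", "pl_LNP_ops")
        opson("lv_LNP_free", "lv_LNP_ops")

        M[I["mps_LNP"], I["lv_LNP_free"]] += p.k_int
        M[I["lv_LNP_free"], I["lv_LNP_free"]] -= p.k_int
        M[I["mps_LNP"], I["mps_LNP"]] -= p.k_deg_LNP

        def vasc_int(lv, li, sV, fu):
            kin = fu * (p.k_in_endo + Lli * (1.0 - sV) / Vlv)
            M[I[li], I[lv]] += kin
            M[I[lv], I[lv]] -= kin
            M[I[lv], I[li]] += p.k_out_exo
            M[I[li], I[li]] -= p.k_out_exo

        vasc_int("lv_LNP_free", "li_LNP_free", sV_LNP, 1.0)
        vasc_int("lv_sgRNA", "li_sgRNA", sV_RNA, p.fu_RNA)
        vasc_int("lv_mRNA", "li_mRNA", sV_RNA, p.fu_RNA)

        for li, pl in (
            ("li_LNP_free", "pl_LNP_free"),
            ("li_sgRNA", "pl_sgRNA"),
            ("li_mRNA", "pl_mRNA"),
        ):
            kl = Lli * (1.0 - sI) / Vli
            M[I[pl], I[li]] += kl
            M[I[li], I[li]] -= kl

        k_out_cell = p.k_out_exo if opt.cell_exocytosis else 0.0
        for li, lc in (("li_sgRNA", "lc_sgRNA"), ("li_mRNA", "lc_mRNA")):
            M[I[lc], I[li]] += p.k_in_endo
            M[I[li], I[li]] -= p.k_in_endo
            M[I[li], I[lc]] += k_out_cell
            M[I[lc], I[lc]] -= k_out_cell

        # receptor: unbinding + turnover are linear; binding is bilinear
        M[I["li_LNP_free"], I["li_LNP_complex"]] += p.k_off_LNP
        M[I["li_LNP_complex"], I["li_LNP_complex"]] -= p.k_off_LNP
        M[I["R_free"], I["li_LNP_complex"]] += p.k_off_LNP / Vli
        M[I["R_free"], I["R_free"]] -= p.k_el
        c[I["R_free"]] = p.k_syn

        M[I["li_LNP_complex"], I["li_LNP_complex"]] -= p.k_deg_DR
        if regimen is not None and regimen.lnp_ratio > 0:
            cargo = opt.cargo_to_cell_fraction * p.k_deg_DR / regimen.lnp_ratio
            M[I["lc_sgRNA"], I["li_LNP_complex"]] += cargo * regimen.frac_sgRNA
            M[I["lc_mRNA"], I["li_LNP_complex"]] += cargo * regimen.frac_mRNA

        M[I["li_LNP_free"], I["li_LNP_free"]] -= p.k_release
        if regimen is not None and regimen.lnp_ratio > 0:
            rel = p.k_release / regimen.lnp_ratio
            M[I["li_sgRNA"], I["li_LNP_free"]] += rel * regimen.frac_sgRNA
            M[I["li_mRNA"], I["li_LNP_free"]] += rel * regimen.frac_mRNA

        for n in ("pl_LNP_free", "lv_LNP_free", "li_LNP_free", "kid_LNP", "rem_LNP"):
            M[I[n], I[n]] -= p.k_deg_LNP
        for n in ("pl_sgRNA", "lv_sgRNA", "li_sgRNA", "kid_sgRNA", "rem_sgRNA", "lc_sgRNA"):
            M[I[n], I[n]] -= p.k_deg_sgRNA
        for n in ("pl_mRNA", "lv_mRNA", "li_mRNA", "rem_mRNA", "lc_mRNA"):
            M[I[n], I[n]] -= p.k_deg_mRNA

        M[I["lc_Cas9"], I["lc_mRNA"]] += p.k_trans
        M[I["lc_Cas9"], I["lc_Cas9"]] -= p.k_deg_Cas_eff
        M[I["lc_Cas9"], I["lc_RNP"]] += p.k_off_RNP
        M[I["lc_RNP"], I["lc_RNP"]] -= p.k_off_RNP

        if opt.renal_clearance_on:
            M[I["kid_LNP"], I["kid_LNP"]] -= p.fu_LNP * Qk / Vk
            M[I["kid_sgRNA"], I["kid_sgRNA"]] -= p.fu_RNA * Qk / Vk

        self._linsys_cache = (key, M, c)
        return M, c

    def rhs(self, t: float, y: np.ndarray, regimen: DoseRegimen | None = None) -> np.ndarray:
        """Full state derivative (ug/h; receptor in ug/mL/h), fast path."""
        if y.shape[-1] != N_PK_STATES:
            raise ValueError(f"state dimension {y.shape[-1]} != {N_PK_STATES}")
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at t={t}")
        M, csrc = self._linear_system(regimen)
        a = np.maximum(y, 0.0)
        d = M @ a
        d += csrc
        p = self.params
        Vli, Vlc = self.phys.V_liver_int, self.phys.V_liver_cell
        # bilinear receptor binding
        b = p.k_on_LNP * p.fu_LNP * a[IDX["li_LNP_free"]] * a[IDX["R_free"]]
        d[IDX["li_LNP_free"]] -= b
        d[IDX["li_LNP_complex"]] += b
        d[IDX["R_free"]] -= b / Vli
        # bilinear RNP assembly (sgRNA drives as a concentration, not consumed)
        F = p.k_on_RNP * (a[IDX["lc_sgRNA"]] / Vlc) * a[IDX["lc_Cas9"]]
        d[IDX["lc_Cas9"]] -= F
        d[IDX["lc_RNP"]] += F
        if regimen is not None and regimen.route == "infusion" and 0.0 <= t < regimen.infusion_duration:
            dur = regimen.infusion_duration
            d[IDX["pl_LNP_free"]] += regimen.amount_LNP / dur
            d[IDX["pl_sgRNA"]] += regimen.amount_sgRNA / dur
            d[IDX["pl_mRNA"]] += regimen.amount_mRNA / dur
        return d

    def rnp_concentration(self, y: np.ndarray) -> float | np.ndarray:
        """Liver-cell RNP concentration (ug/mL), the PD driving signal."""
        return np.asarray(y)[..., IDX["lc_RNP"]] / self.phys.V_liver_cell


def build_model(
    phys: SpeciesPhysiology,
    params: PKParameters,
    topology: ModelTopology | None = None,
    options: ModelOptions | None = None,
) -> PKModel:
    """Assemble a :class:`PKModel` from validated physiology and parameters."""
    return PKModel(
        phys=phys,
        params=params,
        topology=topology if topology is not None else ModelTopology(),
        options=options if options is not None else ModelOptions(),
    )


# ----------------------------------------------------------------------
# Bundled parameter files
# ----------------------------------------------------------------------

def load_parameters(species_or_path: str, with_status: bool = False):
    """Load the bundled (or user) PK parameter set for a species.

    Parameter files annotate each symbol with a fixed/estimated status used
    by the calibration module; pass ``with_status=True`` to receive the
    ``(PKParameters, {name: status})`` pair.
    """
    from pathlib import Path

    key = str(species_or_path)
    if key in ("mouse", "nhp", "human"):
        text = resources.files("crisprqsp.data").joinpath(f"params_{key}.yaml").read_text()
    else:
        path = Path(species_or_path)
        if not path.exists():
            raise ValueError(f"unknown species or missing parameter file: {species_or_path!r}")
        text = path.read_text()
    raw = yaml.safe_load(text)
    entries = raw["parameters"]
    known = {f.name for f in dataclasses.fields(PKParameters)}
    unknown = set(entries) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    values = {k: v["value"] for k, v in entries.items()}
    params = PKParameters(**values)
    if with_status:
        status = {k: v.get("status", "fixed") for k, v in entries.items()}
        return params, status
    return params
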