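"""Individual-level state-transition simulation of 5-year outcomes.

The 5-year horizon is divided into 20 three-month cycles.  Each cycle a
patient may die of background causes, suffer a clinically relevant bleed
(clinically relevant nonmajor, major non-intracranial, or intracranial) or
a recurrent VTE (PE or DVT); acute events last one cycle and can be fatal
or leave a chronic sequela (postthrombotic syndrome after DVT, chronic
thromboembolic pulmonary hypertension after PE, a post-ICH state after
intracranial hemorrhage).  Chronic states are absorbing among themselves;
death is absorbing.  Event ordering within a cycle is death check →
bleeding → recurrence → sequelae, with at most one acute event per cycle;
events across cycles are independent given the constant per-cycle hazards.

QALYs accrue per cycle as (state utility − acute-event disutility, floored
at 0) × 0.25 years; a cycle in which the patient dies accrues nothing (no
half-cycle correction, no discounting).

Treatment dynamics: an on-treatment major bleed stops anticoagulation
permanently; an off-treatment recurrence restarts it (both configurable);
a per-cycle random-discontinuation probability supports the
discontinuation scenario.

Randomness is consumed from a per-patient × per-cycle × per-decision
uniform array drawn from a seed-keyed generator and indexed by patient id,
so results are invariant to cohort ordering and identical uniforms can be
reused across policies (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .risk import CYCLE_YEARS, N_CYCLES, five_year_to_cycle_prob

__all__ = [
    "N_SLOTS",
    "RunResult",
    "Trajectory",
    "cycle_uniforms",
    "simulate_cohort",
    "run_cohort",
    "simulate_patient",
    "expectation_oracle",
]

# uniform slots per patient-cycle
_U_DEATH, _U_BLEED, _U_BLEED_SEV, _U_ICH, _U_BLEED_FATAL, _U_POSTICH = range(6)
_U_VTE, _U_VTE_TYPE, _U_PE_FATAL, _U_SEQUELA, _U_DISC = range(6, 11)
N_SLOTS = 11

# base (inter-cycle) states
_EVENT_FREE, _PTS, _CTEPH, _POST_ICH = range(4)
_BASE_STATE_NAMES = ("event_free", "pts", "cteph", "post_ich")


@dataclass
class RunResult:
    """Cohort-level outcome counts and QALYs for one simulated run."""

    n: int
    label: str
    proportion_treated: float
    recurrences: int
    recurrences_pe: int
    recurrences_dvt: int
    bleeds: int
    bleeds_crnmb: int
    bleeds_major: int
    bleeds_ich: int
    deaths: int
    deaths_background: int
    deaths_pe: int
    deaths_bleed: int
    qalys: float
    per_patient_qalys: np.ndarray | None = None


@dataclass
class Trajectory:
    """Per-cycle history of a single simulated patient."""

    patient_id: int
    records: pd.DataFrame  # cycle, state, treated, utility
    events: list[dict] = field(default_factory=list)

    @property
    def qalys(self) -> float:
        return float(self.records["utility"].sum() * CYCLE_YEARS)


def cycle_uniforms(seed: int, ids: np.ndarray, n_cycles: int = N_CYCLES) -> np.ndarray:
    """Per-patient uniform draws keyed by (seed, patient id).

    A ``(max_id + 1, n_cycles, N_SLOTS)`` block is drawn from a single
    seeded generator and indexed by id, so a patient's stream does not
    depend on cohort order.
    """
    ids = np.asarray(ids, dtype=np.int64)
    rng = np.random.default_rng(seed)
    block = rng.random((int(ids.max()) + 1, n_cycles, N_SLOTS))
    return block[ids]


def _cycle_event_probs(profiles: pd.DataFrame):
    pv_on = five_year_to_cycle_prob(profiles["p_vte_5y_on"].to_numpy())
    pv_off = five_year_to_cycle_prob(profiles["p_vte_5y_off"].to_numpy())
    pb_on = five_year_to_cycle_prob(profiles["p_bleed_5y_on"].to_numpy())
    pb_off = five_year_to_cycle_prob(profiles["p_bleed_5y_off"].to_numpy())
    return pv_on, pv_off, pb_on, pb_off


def simulate_cohort(
    profiles: pd.DataFrame,
    treated: np.ndarray,
    mort_cycle: np.ndarray,
    params: ModelParams,
    uniforms: np.ndarray,
    label: str = "",
    keep_per_patient: bool = False,
    trace: bool = False,
):
    """Vectorised microsimulation of a whole cohort.

    Parameters
    ----------
    profiles : DataFrame with 5-year risks off/on treatment per patient.
    treated : initial extended-anticoagulation flag per patient.
    mort_cycle : (n, 20) conditional background death probability per cycle.
    uniforms : (n, 20, N_SLOTS) uniforms from :func:`cycle_uniforms`.

    Returns a :class:`RunResult`, plus a per-cycle state/treated/utility
    trace when ``trace`` is requested.
    """
    n = len(profiles)
    treated = np.asarray(treated, dtype=bool)
    if treated.shape != (n,):
        raise ValueError("assignment does not cover the cohort")
    if mort_cycle.shape != (n, N_CYCLES) or uniforms.shape != (n, N_CYCLES, N_SLOTS):
        raise ValueError("mortality/uniform array shape mismatch with cohort")
    ev, ut, beh = params.events, params.utilities, params.behavior
    pv_on, pv_off, pb_on, pb_off = _cycle_event_probs(profiles)
    for arr in (pv_on, pv_off, pb_on, pb_off, mort_cycle):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("derived per-cycle probability outside [0, 1]")

    state_util = np.array([ut.baseline, ut.pts, ut.cteph, ut.post_ich])
    alive = np.ones(n, dtype=bool)
    base = np.zeros(n, dtype=np.int8)
    on_trt = treated.copy()
    perm_off = np.zeros(n, dtype=bool)
    qalys = np.zeros(n)
    counts = dict.fromkeys(
        ["rec", "rec_pe", "rec_dvt", "bleed", "crnmb", "major", "ich",
         "d_bg", "d_pe", "d_bleed"], 0,
    )
    trace_state = np.full((n, N_CYCLES), "dead", dtype=object) if trace else None
    trace_trt = np.zeros((n, N_CYCLES), dtype=bool) if trace else None
    trace_util = np.zeros((n, N_CYCLES)) if trace else None

    for k in range(N_CYCLES):
        u = uniforms[:, k, :]
        die_bg = alive & (u[:, _U_DEATH] < mort_cycle[:, k])
        surv = alive & ~die_bg

        pb = np.where(on_trt, pb_on, pb_off)
        bleed = surv & (u[:, _U_BLEED] < pb)
        crnmb = bleed & (u[:, _U_BLEED_SEV] < ev.p_crnmb_given_bleed)
        major = bleed & ~crnmb
        ich = major & (u[:, _U_ICH] < ev.p_ich_given_major)
        major_nonich = major & ~ich
        fatal_bleed = (ich & (u[:, _U_BLEED_FATAL] < ev.cf_ich)) | (
            major_nonich & (u[:, _U_BLEED_FATAL] < ev.cf_major_bleed)
        )
        postich = ich & ~fatal_bleed & (u[:, _U_POSTICH] < ev.p_postich_after_ich)

        pv = np.where(on_trt, pv_on, pv_off)
        rec = surv & ~bleed & (u[:, _U_VTE] < pv)
        pe = rec & (u[:, _U_VTE_TYPE] < ev.p_pe_given_recurrence)
        dvt = rec & ~pe
        fatal_pe = pe & (u[:, _U_PE_FATAL] < ev.cf_pe)
        pts = dvt & (u[:, _U_SEQUELA] < ev.p_pts_after_dvt)
        cteph = pe & ~fatal_pe & (u[:, _U_SEQUELA] < ev.p_cteph_after_pe)

        dies = die_bg | fatal_bleed | fatal_pe
        alive_cycle = alive & ~dies

        util = np.where(alive_cycle, state_util[base], 0.0)
        dis = np.zeros(n)
        dis[crnmb] = ut.dis_crnmb
        dis[major] = ut.dis_major_bleed
        dis[pe] = ut.dis_pe
        dis[dvt] = ut.dis_dvt
        util = np.maximum(util - np.where(alive_cycle, dis, 0.0), 0.0)
        if ut.treatment_multiplier != 1.0:
            util = np.where(on_trt & alive_cycle, util * ut.treatment_multiplier, util)
        qalys += util

        counts["rec"] += int(rec.sum())
        counts["rec_pe"] += int(pe.sum())
        counts["rec_dvt"] += int(dvt.sum())
        counts["bleed"] += int(bleed.sum())
        counts["crnmb"] += int(crnmb.sum())
        counts["major"] += int(major_nonich.sum())
        counts["ich"] += int(ich.sum())
        counts["d_bg"] += int(die_bg.sum())
        counts["d_pe"] += int(fatal_pe.sum())
        counts["d_bleed"] += int(fatal_bleed.sum())

        if trace:
            names = np.full(n, "dead", dtype=object)
            names[alive_cycle] = np.array(_BASE_STATE_NAMES, dtype=object)[base[alive_cycle]]
            names[crnmb & alive_cycle] = "crnmb"
            names[major_nonich & alive_cycle] = "major_bleed"
            names[ich & alive_cycle] = "ich"
            names[pe & alive_cycle] = "recurrent_pe"
            names[dvt & alive_cycle] = "recurrent_dvt"
            trace_state[:, k] = names
            trace_trt[:, k] = on_trt & alive_cycle
            trace_util[:, k] = util

        # chronic sequelae take effect from the next cycle
        base[pts] = _PTS
        base[cteph] = _CTEPH
        base[postich] = _POST_ICH

        # treatment transitions from start-of-cycle status
        stop_bleed = (
            on_trt & major & ~fatal_bleed if beh.stop_after_major_bleed else np.zeros(n, bool)
        )
        disc = (
            on_trt & surv & (u[:, _U_DISC] < beh.p_discontinue_cycle)
            if beh.p_discontinue_cycle > 0
            else np.zeros(n, bool)
        )
        restart = (
            (~on_trt) & ~perm_off & rec & ~fatal_pe
            if beh.restart_after_recurrence
            else np.zeros(n, bool)
        )
        stopping = stop_bleed | disc
        on_trt = (on_trt & ~stopping) | restart
        perm_off = perm_off | stopping
        alive = alive_cycle

    result = RunResult(
        n=n,
        label=label,
        proportion_treated=float(treated.mean()),
        recurrences=counts["rec"],
        recurrences_pe=counts["rec_pe"],
        recurrences_dvt=counts["rec_dvt"],
        bleeds=counts["bleed"],
        bleeds_crnmb=counts["crnmb"],
        bleeds_major=counts["major"],
        bleeds_ich=counts["ich"],
        deaths=counts["d_bg"] + counts["d_pe"] + counts["d_bleed"],
        deaths_background=counts["d_bg"],
        deaths_pe=counts["d_pe"],
        deaths_bleed=counts["d_bleed"],
        qalys=float(qalys.sum() * CYCLE_YEARS),
        per_patient_qalys=qalys * CYCLE_YEARS if keep_per_patient else None,
    )
    if trace:
        return result, (trace_state, trace_trt, trace_util)
    return result


def run_cohort(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    treated: np.ndarray,
    mort_cycle: np.ndarray,
    params: ModelParams,
    seed: int,
    label: str = "",
    keep_per_patient: bool = False,
) -> RunResult:
    """Simulate a cohort with per-patient substreams derived from ``seed``.

    Deterministic given the seed; stable under cohort reordering because
    uniforms are keyed by patient id.
    """
    if len(cohort) != len(profiles) or len(cohort) != len(treated):
        raise ValueError("cohort, profiles and assignment sizes do not match")
    uniforms = cycle_uniforms(seed, cohort["id"].to_numpy())
    return simulate_cohort(
        profiles, treated, mort_cycle, params, uniforms,
        label=label, keep_per_patient=keep_per_patient,
    )


def simulate_patient(
    patient_id: int,
    profile: pd.Series,
    treated: bool,
    mort_probs: np.ndarray,
    params: ModelParams,
    seed: int,
) -> Trajectory:
    """Simulate one patient and return the full cycle-by-cycle trajectory."""
    profiles = pd.DataFrame([profile])
    uniforms = cycle_uniforms(seed, np.array([patient_id]))
    result, (states, trts, utils) = simulate_cohort(
        profiles,
        np.array([treated]),
        np.asarray(mort_probs, dtype=float).reshape(1, -1),
        params,
        uniforms,
        trace=True,
    )
    records = pd.DataFrame(
        {
            "cycle": np.arange(N_CYCLES),
            "state": states[0],
            "treated": trts[0],
            "utility": utils[0],
        }
    )
    events = [
        {"cycle": int(row.cycle), "type": str(row.state)}
        for row in records.itertuples()
        if row.state in {"crnmb", "major_bleed", "ich", "recurrent_pe", "recurrent_dvt"}
    ]
    return Trajectory(patient_id=patient_id, records=records, events=events)


# --- deterministic expectation twin -------------------------------------

_S_ON, _S_OFF_R, _S_OFF_P = range(3)


def expectation_oracle(
    profile: pd.Series | dict,
    treated: bool,
    mort_probs: np.ndarray,
    params: ModelParams,
) -> dict[str, float]:
    """Exact expected outcomes for one patient by forward propagation.

    Propagates the joint distribution over (base state × treatment status)
    through the same per-cycle event tree the microsimulation draws from,
    accumulating expected event counts, deaths and QALYs analytically.
    Serves as the deterministic Markov-cohort twin of the stochastic
    engine.
    """
    ev, ut, beh = params.events, params.utilities, params.behavior
    pv = {
        True: five_year_to_cycle_prob(float(profile["p_vte_5y_on"])),
        False: five_year_to_cycle_prob(float(profile["p_vte_5y_off"])),
    }
    pb = {
        True: five_year_to_cycle_prob(float(profile["p_bleed_5y_on"])),
        False: five_year_to_cycle_prob(float(profile["p_bleed_5y_off"])),
    }
    mort_probs = np.asarray(mort_probs, dtype=float)
    state_util = (ut.baseline, ut.pts, ut.cteph, ut.post_ich)

    occ = np.zeros((4, 3))
    occ[_EVENT_FREE, _S_ON if treated else _S_OFF_R] = 1.0
    dead = 0.0
    out = dict.fromkeys(
        ["recurrences", "recurrences_pe", "recurrences_dvt", "bleeds",
         "bleeds_crnmb", "bleeds_major", "bleeds_ich",
         "deaths_background", "deaths_pe", "deaths_bleed", "qalys"], 0.0,
    )

    d = beh.p_discontinue_cycle
    for k in range(len(mort_probs)):
        q = mort_probs[k]
        new_occ = np.zeros((4, 3))

        for b in range(4):
            for s in range(3):
                m = occ[b, s]
                if m == 0.0:
                    continue
                on = s == _S_ON
                mult = ut.treatment_multiplier if on else 1.0
                u_base = state_util[b]

                out["deaths_background"] += m * q
                m1 = m * (1.0 - q)
                p_bleed = pb[on]
                p_vte = pv[on]

                # treatment status carried to next cycle, before event effects
                def _next_s(stop: bool = False, restart: bool = False) -> dict[int, float]:
                    if s == _S_OFF_P:
                        return {_S_OFF_P: 1.0}
                    if s == _S_OFF_R:
                        return {_S_ON: 1.0} if restart else {_S_OFF_R: 1.0}
                    if stop:
                        return {_S_OFF_P: 1.0}
                    if d > 0:
                        return {_S_OFF_P: d, _S_ON: 1.0 - d}
                    return {_S_ON: 1.0}

                def _deposit(mass: float, b_new: int, **kw) -> None:
                    for s_new, w in _next_s(**kw).items():
                        new_occ[b_new, s_new] += mass * w

                def _accrue(mass: float, dis: float) -> None:
                    out["qalys"] += mass * max(u_base - dis, 0.0) * mult * CYCLE_YEARS

                # --- bleeding branch
                mb = m1 * p_bleed
                out["bleeds"] += mb
                m_crnmb = mb * ev.p_crnmb_given_bleed
                out["bleeds_crnmb"] += m_crnmb
                _accrue(m_crnmb, ut.dis_crnmb)
                _deposit(m_crnmb, b)

                m_major = mb * (1.0 - ev.p_crnmb_given_bleed)
                m_ich = m_major * ev.p_ich_given_major
                m_mni = m_major - m_ich
                out["bleeds_ich"] += m_ich
                out["bleeds_major"] += m_mni

                out["deaths_bleed"] += m_mni * ev.cf_major_bleed + m_ich * ev.cf_ich
                m_mni_surv = m_mni * (1.0 - ev.cf_major_bleed)
                _accrue(m_mni_surv, ut.dis_major_bleed)
                _deposit(m_mni_surv, b, stop=beh.stop_after_major_bleed)

                m_ich_surv = m_ich * (1.0 - ev.cf_ich)
                _accrue(m_ich_surv, ut.dis_major_bleed)
                m_pi = m_ich_surv * ev.p_postich_after_ich
                _deposit(m_pi, _POST_ICH, stop=beh.stop_after_major_bleed)
                _deposit(m_ich_surv - m_pi, b, stop=beh.stop_after_major_bleed)

                # --- recurrence branch (no bleed this cycle)
                mr = m1 * (1.0 - p_bleed) * p_vte
                out["recurrences"] += mr
                restart = beh.restart_after_recurrence
                m_pe = mr * ev.p_pe_given_recurrence
                m_dvt = mr - m_pe
                out["recurrences_pe"] += m_pe
                out["recurrences_dvt"] += m_dvt

                out["deaths_pe"] += m_pe * ev.cf_pe
                m_pe_surv = m_pe * (1.0 - ev.cf_pe)
                _accrue(m_pe_surv, ut.dis_pe)
                m_ct = m_pe_surv * ev.p_cteph_after_pe
                _deposit(m_ct, _CTEPH, restart=restart)
                _deposit(m_pe_surv - m_ct, b, restart=restart)

                _accrue(m_dvt, ut.dis_dvt)
                m_pts = m_dvt * ev.p_pts_after_dvt
                _deposit(m_pts, _PTS, restart=restart)
                _deposit(m_dvt - m_pts, b, restart=restart)

                # --- event-free branch
                m0 = m1 * (1.0 - p_bleed) * (1.0 - p_vte)
                _accrue(m0, 0.0)
                _deposit(m0, b)

        dead = 1.0 - new_occ.sum()
        occ = new_occ

    out["deaths"] = out["deaths_background"] + out["deaths_pe"] + out["deaths_bleed"]
    assert abs(out["deaths"] - dead) < 1e-9
    return out
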