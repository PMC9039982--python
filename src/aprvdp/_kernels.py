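"""Numba kernels for the multi-compartment lung simulator.

Everything here operates on plain float64/int8 arrays so the per-millisecond
time stepping stays cheap.  The physics: 100 parallel alveolar compartments
behind a common proximal node, a series dead-space gas column between mouth
and node, per-compartment recruitment gated by threshold opening pressure,
and alveolar-capillary gas exchange against a fixed mixed-venous composition
(which the Python wrapper relaxes to its steady state between breaths).

Pressures cmH2O, volumes L, flows L/s, blood-gas tensions mmHg,
blood contents mL gas per L blood.  Gas fractions are on a dry-gas basis,
tension = fraction * PB_DRY.
"""

import numpy as np
from numba import njit

PB_DRY = 713.0  # barometric minus saturated water vapour pressure at 37 C, mmHg

# measurement slot indices for the per-cycle accumulator vector
M_PIP = 0        # max ventilator (airway-opening) pressure, cmH2O
M_PPLAT = 1      # max mean lung pressure, cmH2O
M_PEEPTOT = 2    # mean lung pressure at end of cycle, cmH2O
M_VFRC = 3       # min total alveolar volume, L
M_PEFR = 4       # peak expiratory flow magnitude, L/s
M_EEFR = 5       # expiratory flow magnitude at the final expiratory sample, L/s
M_VREL = 6       # exhaled volume, L
M_VINSP = 7      # inhaled volume, L
M_PETCO2 = 8     # CO2 tension of gas at the mouth at end expiration, mmHg
M_ACC_O2 = 9     # integral of q*CcO2 over open compartments, mL
M_ACC_CO2 = 10   # integral of q*CcCO2 over open compartments, mL
M_ACC_Q = 11     # integral of perfusion through open compartments, L
M_MO2_IN = 12    # O2 volume in through the mouth, L
M_MO2_OUT = 13   # O2 volume out through the mouth, L
M_MCO2_IN = 14   # CO2 volume in through the mouth, L
M_MCO2_OUT = 15  # CO2 volume out through the mouth, L
M_PINSPF = 16    # peak inspiratory flow magnitude, L/s
N_MEAS = 17


@njit(cache=True)
def o2_saturation(p):
    """Severinghaus (1979) haemoglobin O2 saturation from tension (mmHg)."""
    if p <= 0.0:
        return 0.0
    x = p * (p * p + 150.0)
    return x / (x + 23400.0)


@njit(cache=True)
def o2_blood_content(p, hb):
    """O2 content of blood, mL/L, from tension (mmHg) and haemoglobin (g/L)."""
    return 1.34 * hb * o2_saturation(p) + 0.03 * p


@njit(cache=True)
def co2_blood_content(p):
    """CO2 content of blood, mL/L; linearised dissociation about 40 mmHg."""
    c = 480.0 + 5.5 * (p - 40.0)
    return c if c > 0.0 else 0.0


@njit(cache=True)
def o2_tension_from_content(content, hb):
    """Invert o2_blood_content by bisection."""
    if content <= 0.0:
        return 0.0
    lo = 0.0
    hi = 800.0
    if o2_blood_content(hi, hb) <= content:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if o2_blood_content(mid, hb) < content:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def co2_tension_from_content(content):
    p = 40.0 + (content - 480.0) / 5.5
    return p if p > 0.0 else 0.0


@njit(cache=True)
def elastic_pressure(v, p_ext, k_stiff, beta, c0, v0):
    """Alveolar recoil + extrinsic pressure at gas volume v.

    Sigmoid pressure-volume relation: recoil = exp(k)*sinh(beta*(v-v0))
    / (beta*c0), softest (compliance c0*exp(-k)) at the resting volume v0
    and stiffening symmetrically away from it.  beta == 0 gives the exact
    linear limit with compliance c0*exp(-k_stiff).
    """
    if beta == 0.0:
        return p_ext + np.exp(k_stiff) * (v - v0) / c0
    return p_ext + np.exp(k_stiff) * np.sinh(beta * (v - v0)) / (beta * c0)


@njit(cache=True)
def local_compliance(v, k_stiff, beta, c0, v0):
    """dV/dP of the compartment PV curve at volume v."""
    if beta == 0.0:
        return c0 * np.exp(-k_stiff)
    return c0 * np.exp(-k_stiff) / np.cosh(beta * (v - v0))


@njit(cache=True)
def equilibrium_volume(p_alv, p_ext, k_stiff, beta, c0, v0, v_min):
    """Volume at which elastic_pressure equals p_alv, floored at v_min."""
    rec = (p_alv - p_ext) * np.exp(-k_stiff)
    if beta == 0.0:
        v = v0 + rec * c0
    else:
        v = v0 + np.arcsinh(beta * c0 * rec) / beta
    if v < v_min:
        v = v_min
    return v


@njit(cache=True)
def init_meas(meas):
    for i in range(N_MEAS):
        meas[i] = 0.0
    meas[M_PIP] = -1e30
    meas[M_PPLAT] = -1e30
    meas[M_VFRC] = 1e30
    meas[M_PETCO2] = np.nan
    meas[M_EEFR] = 0.0


@njit(cache=True)
def advance(
    V, vo2, vco2, is_open, q_comp,
    ds_o2, ds_co2, v_slice,
    p_ext, k_stiff, top, r_b,
    mode, val,
    dt, beta, c0, v0, v_close, r_central, exp_factor,
    fio2, hb, cv_o2, cv_co2, q_perf, gas_every,
    q_mouth_prev,
    tr_paw, tr_plung, tr_flow, tr_vol, sample_every,
    meas,
):
    """Advance the lung by len(mode) fixed steps of size dt.

    mode[s] == 0: val[s] is the applied airway-opening pressure (cmH2O);
    mode[s] == 1: val[s] is the applied mouth flow (L/s, inspiratory > 0).

    State arrays (V, vo2, vco2, is_open, q_comp, ds_*) are updated in place;
    per-cycle measurements accumulate into ``meas`` (see M_* indices; caller
    pre-fills with init_meas).  Traces are written every ``sample_every``
    steps.  Returns (final mouth flow, number of trace samples written).
    """
    n = V.shape[0]
    nds = ds_o2.shape[0]
    n_steps = mode.shape[0]

    palv = np.empty(n)
    gcond = np.empty(n)
    qm = q_mouth_prev
    n_written = 0
    dtg = gas_every * dt

    r_impl = np.empty(n)

    for s in range(n_steps):
        # --- compartment recoil pressures (open compartments only); the
        # dt/C term makes the per-compartment volume update semi-implicit
        # (backward Euler in the local linearisation), which keeps stiff
        # compartments stable at the fixed step size
        for i in range(n):
            if is_open[i] == 1:
                palv[i] = elastic_pressure(
                    V[i], p_ext[i], k_stiff[i], beta, c0, v0)
                r_impl[i] = dt / local_compliance(
                    V[i], k_stiff[i], beta, c0, v0)

        # --- two-pass flow solve: the expiratory-resistance regime of each
        # branch is taken from the flow direction the solve itself produces
        # (first guess: previous step's directions)
        qm_sign = qm
        p_node = 0.0
        p_ao = 0.0
        q_tot = 0.0
        for _pass in range(2):
            gsum = 0.0
            gpsum = 0.0
            for i in range(n):
                if is_open[i] == 1:
                    fac = exp_factor if q_comp[i] < 0.0 else 1.0
                    g = 1.0 / (r_b[i] * fac + r_impl[i])
                    gcond[i] = g
                    gsum += g
                    gpsum += g * palv[i]
                else:
                    gcond[i] = 0.0
            rc_eff = r_central * (exp_factor if qm_sign < 0.0 else 1.0)
            if mode[s] == 0:
                p_ao = val[s]
                if gsum > 0.0:
                    p_node = (p_ao / rc_eff + gpsum) / (1.0 / rc_eff + gsum)
                else:
                    p_node = p_ao
                q_tot = (p_ao - p_node) / rc_eff
            else:
                q_tot = val[s]
                if gsum > 0.0:
                    p_node = (q_tot + gpsum) / gsum
                else:
                    # flow imposed on a fully derecruited lung: the proximal
                    # pressure rises until something opens
                    p_node = 100.0
                p_ao = p_node + q_tot * rc_eff
            if _pass == 0:
                # refresh direction guesses from this solve
                qm_sign = q_tot
                for i in range(n):
                    if gcond[i] > 0.0:
                        q_comp[i] = (p_node - palv[i]) * gcond[i]

        # --- recruitment: opening by proximal pressure (takes effect next step)
        for i in range(n):
            if is_open[i] == 0 and p_node >= top[i]:
                is_open[i] = 1
                q_comp[i] = 0.0

        # --- per-compartment flows; collect exhaled mixture at the node
        q_exh = 0.0
        exh_o2 = 0.0
        exh_co2 = 0.0
        for i in range(n):
            g = gcond[i]
            if g > 0.0:
                q = (p_node - palv[i]) * g
                q_comp[i] = q
                if q < 0.0:
                    fo = vo2[i] / V[i]
                    fc = vco2[i] / V[i]
                    q_exh -= q
                    exh_o2 -= q * fo
                    exh_co2 -= q * fc
            else:
                q_comp[i] = 0.0

        # composition of gas available at the node for inflowing compartments
        src = q_exh + (q_tot if q_tot > 0.0 else 0.0)
        if src > 1e-12:
            if q_tot > 0.0:
                fin_o2 = (exh_o2 + q_tot * ds_o2[nds - 1]) / src
                fin_co2 = (exh_co2 + q_tot * ds_co2[nds - 1]) / src
            else:
                fin_o2 = exh_o2 / q_exh
                fin_co2 = exh_co2 / q_exh
        else:
            fin_o2 = ds_o2[nds - 1]
            fin_co2 = ds_co2[nds - 1]

        # --- volume and species update
        for i in range(n):
            if gcond[i] > 0.0:
                q = q_comp[i]
                if q >= 0.0:
                    vo2[i] += q * dt * fin_o2
                    vco2[i] += q * dt * fin_co2
                else:
                    fo = vo2[i] / V[i]
                    fc = vco2[i] / V[i]
                    vo2[i] += q * dt * fo
                    vco2[i] += q * dt * fc
                V[i] += q * dt
                if vo2[i] < 0.0:
                    vo2[i] = 0.0
                if vco2[i] < 0.0:
                    vco2[i] = 0.0
                if V[i] <= v_close:
                    is_open[i] = 0
                    q_comp[i] = 0.0
                    if V[i] < 1e-6:
                        V[i] = 1e-6

        # --- series dead space: chain of well-mixed slices (slice 0 at mouth)
        if q_tot > 0.0:
            a = q_tot * dt / v_slice
            if a > 1.0:
                a = 1.0
            prev_o = fio2
            prev_c = 0.0
            for j in range(nds):
                old_o = ds_o2[j]
                old_c = ds_co2[j]
                ds_o2[j] += a * (prev_o - old_o)
                ds_co2[j] += a * (prev_c - old_c)
                prev_o = old_o
                prev_c = old_c
            meas[M_MO2_IN] += q_tot * dt * fio2
            meas[M_VINSP] += q_tot * dt
            if q_tot > meas[M_PINSPF]:
                meas[M_PINSPF] = q_tot
        elif q_tot < 0.0:
            qe = -q_tot
            a = qe * dt / v_slice
            if a > 1.0:
                a = 1.0
            if q_exh > 1e-12:
                prev_o = exh_o2 / q_exh
                prev_c = exh_co2 / q_exh
            else:
                prev_o = ds_o2[nds - 1]
                prev_c = ds_co2[nds - 1]
            mouth_o2 = ds_o2[0]
            mouth_co2 = ds_co2[0]
            for j in range(nds - 1, -1, -1):
                old_o = ds_o2[j]
                old_c = ds_co2[j]
                ds_o2[j] += a * (prev_o - old_o)
                ds_co2[j] += a * (prev_c - old_c)
                prev_o = old_o
                prev_c = old_c
            meas[M_MO2_OUT] += qe * dt * mouth_o2
            meas[M_MCO2_OUT] += qe * dt * mouth_co2
            meas[M_VREL] += qe * dt
            meas[M_PETCO2] = mouth_co2 * PB_DRY
            meas[M_EEFR] = qe
            if qe > meas[M_PEFR]:
                meas[M_PEFR] = qe

        # --- alveolar-capillary gas exchange (no net volume change; the
        # implicit N2/H2O balance absorbs the respiratory-quotient deficit)
        if s % gas_every == 0:
            for i in range(n):
                if is_open[i] == 1 and V[i] > 1e-5:
                    po2 = vo2[i] / V[i] * PB_DRY
                    pco2 = vco2[i] / V[i] * PB_DRY
                    cc_o = o2_blood_content(po2, hb)
                    cc_c = co2_blood_content(pco2)
                    fl_o = q_perf * (cc_o - cv_o2) * dtg * 1e-3
                    if fl_o > vo2[i]:
                        fl_o = vo2[i]
                    fl_c = q_perf * (cv_co2 - cc_c) * dtg * 1e-3
                    vo2[i] -= fl_o
                    vco2[i] += fl_c
                    if vco2[i] < 0.0:
                        vco2[i] = 0.0
                    meas[M_ACC_O2] += q_perf * cc_o * dtg
                    meas[M_ACC_CO2] += q_perf * cc_c * dtg
                    meas[M_ACC_Q] += q_perf * dtg

        # --- mean (volume-weighted) lung pressure over communicating lung
        vtot = 0.0
        vopen = 0.0
        pw = 0.0
        for i in range(n):
            vtot += V[i]
            if gcond[i] > 0.0:
                vopen += V[i]
                pw += V[i] * palv[i]
        plung = pw / vopen if vopen > 0.0 else p_node

        if p_ao > meas[M_PIP]:
            meas[M_PIP] = p_ao
        if plung > meas[M_PPLAT]:
            meas[M_PPLAT] = plung
        if vtot < meas[M_VFRC]:
            meas[M_VFRC] = vtot
        meas[M_PEEPTOT] = plung

        if s % sample_every == 0:
            tr_paw[n_written] = p_ao
            tr_plung[n_written] = plung
            tr_flow[n_written] = q_tot
            tr_vol[n_written] = vtot
            n_written += 1

        qm = q_tot

    return qm, n_written
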