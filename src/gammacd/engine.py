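"""Fixed-step integration engine for the laminar network.

Numerical scheme (the integrator contract of this package):

* channel gating variables advance by exponential Euler against their
  instantaneous steady state and time constant;
* the voltage/cable system advances by backward Euler with conductances
  frozen over the step, solved exactly per step on each cell's tree with a
  Hines elimination (segments are ordered parent-before-child);
* two-state exponential synapses (rise/decay pair) are advanced analytically
  between events, so event superposition is exact to machine precision;
* recurrent spikes are detected as upward threshold crossings of somatic
  voltage and delivered after a fixed synaptic delay through a ring buffer.

The default step of 0.025 ms is also the output step.  All state is float64
and fully determined by the inputs, so runs are bit-reproducible.

Units: mV, ms, uS, nA, nF; segment areas in cm^2; dipole output in nAm
(1 nA * 1 um = 1e-6 nAm).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

AMPA = 0
GABA_A = 1

# Traub-style voltage shift for the fast Na/K spike currents
VTRAUB = -63.0

# Temperature adjustment of gating kinetics at 37 C.  The rate constants
# below are written at each mechanism's reference temperature (Traub-lineage
# Na/K at 36 C, Mainen-lineage Kdr/Km/Ca/KCa at 23 C with q10 = 2.3,
# Huguenard CaT at 24 C with q10 = 5 (activation) / 3 (inactivation)), so
# each family carries its canonical q10 factor.
TADJ_HH2 = 3.0 ** ((37.0 - 36.0) / 10.0)        # ~1.12
TADJ_MAINEN = 2.3 ** ((37.0 - 23.0) / 10.0)     # ~3.21
TADJ_CAT_M = 5.0 ** ((37.0 - 24.0) / 10.0)      # ~8.1
TADJ_CAT_H = 3.0 ** ((37.0 - 24.0) / 10.0)      # ~4.2


class NumericalInstability(RuntimeError):
    """Voltage left the physical range during integration."""

    def __init__(self, seg: int, step: int, dt: float):
        self.segment = int(seg)
        self.time_ms = (step + 1) * dt
        super().__init__(
            f"voltage instability (|v| > 200 mV) in segment {seg} "
            f"at t = {self.time_ms:.3f} ms")


@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x / (exp(x/y) - 1), stable near x = 0
    if abs(x / y) < 1e-6:
        return y - x / 2.0
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True, inline="always")
def _linoid(x, y):
    # x / (1 - exp(-x/y)), stable near x = 0
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True, inline="always")
def _exp_euler(x, xinf, tau, dt):
    return xinf + (x - xinf) * math.exp(-dt / tau)


@njit(cache=True)
def _init_gates(v, gates, cai_rest):
    """Steady-state gating values at voltage v (per segment)."""
    n_seg = v.shape[0]
    for s in range(n_seg):
        u = v[s] - VTRAUB
        am = 0.32 * _vtrap(13.0 - u, 4.0)
        bm = 0.28 * _vtrap(u - 40.0, 5.0)
        ah = 0.128 * math.exp((17.0 - u) / 18.0)
        bh = 4.0 / (1.0 + math.exp((40.0 - u) / 5.0))
        an = 0.032 * _vtrap(15.0 - u, 5.0)
        bn = 0.5 * math.exp((10.0 - u) / 40.0)
        gates[0, s] = am / (am + bm)          # Na m
        gates[1, s] = ah / (ah + bh)          # Na h
        gates[2, s] = an / (an + bn)          # K n
        vv = v[s]
        a = 0.02 * _linoid(vv - 25.0, 9.0)
        b = 0.002 * _linoid(25.0 - vv, 9.0)
        gates[3, s] = a / (a + b)             # Kdr n
        a = 0.001 * _linoid(vv + 30.0, 9.0)
        b = 0.001 * _linoid(-(vv + 30.0), 9.0)
        gates[4, s] = a / (a + b)             # Km p
        a = 0.055 * _vtrap(-27.0 - vv, 3.8)
        b = 0.94 * math.exp((-75.0 - vv) / 17.0)
        gates[5, s] = a / (a + b)             # Ca m
        a = 4.57e-4 * math.exp((-13.0 - vv) / 50.0)
        b = 0.0065 / (math.exp((-15.0 - vv) / 28.0) + 1.0)
        gates[6, s] = a / (a + b)             # Ca h
        gates[7, s] = 1.0 / (1.0 + math.exp(-(vv + 57.0) / 6.2))   # CaT m
        gates[8, s] = 1.0 / (1.0 + math.exp((vv + 81.0) / 4.0))    # CaT h
        gates[9, s] = 1.0 / (1.0 + math.exp((vv + 75.0) / 5.5))    # h (ar) gate
        a = 0.05 * cai_rest
        gates[10, s] = a / (a + 0.02)         # KCa n


@njit(cache=True)
def _run(dt, n_steps,
         parent, g_ax, d_static, cmdt, area,
         g_na, g_k, g_kdr, g_km, g_leak, g_ca, g_cat, g_h, g_kca,
         e_na, e_k, e_ca, e_h, e_leak,
         ca_tau, ca_rest, ca_drive_factor,
         syn_decay_r, syn_decay_d, syn_peak_factor, e_syn,
         soma_idx, refractory_steps,
         conn_ptr, conn_seg, conn_w, conn_rec, delay_steps,
         ev_step, ev_seg, ev_w, ev_rec,
         i_tonic, inj_seg, inj_traces,
         dip_seg, dip_layer, n_layers, z_um,
         gaba_seg, gaba_layer,
         rec_idx, v, gates, cai,
         spike_threshold, max_spikes):
    n_seg = v.shape[0]
    n_cells = soma_idx.shape[0]
    n_rec = rec_idx.shape[0]

    sA = np.zeros((2, n_seg))
    sB = np.zeros((2, n_seg))
    pend = np.zeros((2, delay_steps, n_seg))

    d = np.empty(n_seg)
    r = np.empty(n_seg)

    dip = np.zeros((n_steps + 1, n_layers))
    gaba_rec = np.zeros((n_steps + 1, n_layers))
    v_rec = np.empty((n_steps + 1, n_rec))
    for k in range(n_rec):
        v_rec[0, k] = v[rec_idx[k]]

    spike_cell = np.empty(max_spikes, np.int64)
    spike_time = np.empty(max_spikes, np.float64)
    n_spikes = 0
    prev_soma = np.empty(n_cells)
    last_spike = np.full(n_cells, -10**9, np.int64)
    for c in range(n_cells):
        prev_soma[c] = v[soma_idx[c]]

    ev_ptr = 0
    n_ev = ev_step.shape[0]
    n_inj = inj_seg.shape[0]

    fac_ca = math.exp(-dt / ca_tau)

    for step in range(n_steps):
        # --- synapses: analytic decay, then deliver increments due this step
        for s in range(n_seg):
            sA[0, s] *= syn_decay_r[0, s]; sB[0, s] *= syn_decay_d[0, s]
            sA[1, s] *= syn_decay_r[1, s]; sB[1, s] *= syn_decay_d[1, s]
        slot = step % delay_steps
        for s in range(n_seg):
            w = pend[0, slot, s]
            if w != 0.0:
                inc = w * syn_peak_factor[0, s]
                sA[0, s] += inc; sB[0, s] += inc
                pend[0, slot, s] = 0.0
            w = pend[1, slot, s]
            if w != 0.0:
                inc = w * syn_peak_factor[1, s]
                sA[1, s] += inc; sB[1, s] += inc
                pend[1, slot, s] = 0.0
        while ev_ptr < n_ev and ev_step[ev_ptr] <= step:
            if ev_step[ev_ptr] == step:
                rc = ev_rec[ev_ptr]
                s = ev_seg[ev_ptr]
                inc = ev_w[ev_ptr] * syn_peak_factor[rc, s]
                sA[rc, s] += inc
                sB[rc, s] += inc
            ev_ptr += 1

        # --- membrane physics per segment
        for s in range(n_seg):
            vv = v[s]
            g_tot = g_leak[s]
            ge = g_leak[s] * e_leak[s]
            ica_abs = 0.0

            if g_na[s] > 0.0:
                u = vv - VTRAUB
                am = 0.32 * _vtrap(13.0 - u, 4.0)
                bm = 0.28 * _vtrap(u - 40.0, 5.0)
                ah = 0.128 * math.exp((17.0 - u) / 18.0)
                bh = 4.0 / (1.0 + math.exp((40.0 - u) / 5.0))
                an = 0.032 * _vtrap(15.0 - u, 5.0)
                bn = 0.5 * math.exp((10.0 - u) / 40.0)
                m = _exp_euler(gates[0, s], am / (am + bm),
                               1.0 / ((am + bm) * TADJ_HH2), dt)
                h = _exp_euler(gates[1, s], ah / (ah + bh),
                               1.0 / ((ah + bh) * TADJ_HH2), dt)
                n = _exp_euler(gates[2, s], an / (an + bn),
                               1.0 / ((an + bn) * TADJ_HH2), dt)
                gates[0, s] = m; gates[1, s] = h; gates[2, s] = n
                g = g_na[s] * m * m * m * h
                g_tot += g; ge += g * e_na
                if g_k[s] > 0.0:
                    g = g_k[s] * n * n * n * n
                    g_tot += g; ge += g * e_k

            if g_kdr[s] > 0.0:
                a = 0.02 * _linoid(vv - 25.0, 9.0)
                b = 0.002 * _linoid(25.0 - vv, 9.0)
                x = _exp_euler(gates[3, s], a / (a + b),
                               1.0 / ((a + b) * TADJ_MAINEN), dt)
                gates[3, s] = x
                g = g_kdr[s] * x
                g_tot += g; ge += g * e_k

            if g_km[s] > 0.0:
                a = 0.001 * _linoid(vv + 30.0, 9.0)
                b = 0.001 * _linoid(-(vv + 30.0), 9.0)
                x = _exp_euler(gates[4, s], a / (a + b),
                               1.0 / ((a + b) * TADJ_MAINEN), dt)
                gates[4, s] = x
                g = g_km[s] * x
                g_tot += g; ge += g * e_k

            if g_ca[s] > 0.0:
                a = 0.055 * _vtrap(-27.0 - vv, 3.8)
                b = 0.94 * math.exp((-75.0 - vv) / 17.0)
                m = _exp_euler(gates[5, s], a / (a + b),
                               1.0 / ((a + b) * TADJ_MAINEN), dt)
                a = 4.57e-4 * math.exp((-13.0 - vv) / 50.0)
                b = 0.0065 / (math.exp((-15.0 - vv) / 28.0) + 1.0)
                h = _exp_euler(gates[6, s], a / (a + b),
                               1.0 / ((a + b) * TADJ_MAINEN), dt)
                gates[5, s] = m; gates[6, s] = h
                g = g_ca[s] * m * m * h
                g_tot += g; ge += g * e_ca
                ica_abs += g * (vv - e_ca)

            if g_cat[s] > 0.0:
                minf = 1.0 / (1.0 + math.exp(-(vv + 57.0) / 6.2))
                hinf = 1.0 / (1.0 + math.exp((vv + 81.0) / 4.0))
                taum = 0.612 + 1.0 / (math.exp(-(vv + 132.0) / 16.7)
                                      + math.exp((vv + 16.8) / 18.2))
                if vv < -81.0:
                    tauh = math.exp((vv + 467.0) / 66.6)
                else:
                    tauh = 28.0 + math.exp(-(vv + 22.0) / 10.5)
                m = _exp_euler(gates[7, s], minf, taum / TADJ_CAT_M, dt)
                h = _exp_euler(gates[8, s], hinf, tauh / TADJ_CAT_H, dt)
                gates[7, s] = m; gates[8, s] = h
                g = g_cat[s] * m * m * h
                g_tot += g; ge += g * e_ca
                ica_abs += g * (vv - e_ca)

            if g_h[s] > 0.0:
                minf = 1.0 / (1.0 + math.exp((vv + 75.0) / 5.5))
                tau = 1.0 / (math.exp(-14.59 - 0.086 * vv)
                             + math.exp(-1.87 + 0.0701 * vv))
                m = _exp_euler(gates[9, s], minf, tau, dt)
                gates[9, s] = m
                g = g_h[s] * m
                g_tot += g; ge += g * e_h

            if g_kca[s] > 0.0:
                a = 0.05 * cai[s]
                b = 0.02
                x = _exp_euler(gates[10, s], a / (a + b),
                               1.0 / ((a + b) * TADJ_MAINEN), dt)
                gates[10, s] = x
                g = g_kca[s] * x
                g_tot += g; ge += g * e_k

            if g_ca[s] > 0.0 or g_cat[s] > 0.0:
                # calcium pool: influx from ICa (nA -> mA/cm^2), first-order return
                ica_dens = ica_abs / area[s] * 1e-6
                drive = -ica_dens * ca_drive_factor
                if drive < 0.0:
                    drive = 0.0
                cai[s] = ca_rest + drive * ca_tau + (
                    cai[s] - ca_rest - drive * ca_tau) * fac_ca

            g0 = sB[0, s] - sA[0, s]
            g1 = sB[1, s] - sA[1, s]
            g_tot += g0 + g1
            ge += g0 * e_syn[0] + g1 * e_syn[1]

            d[s] = d_static[s] + g_tot
            r[s] = cmdt[s] * vv + ge + i_tonic[s]

        for k in range(n_inj):
            r[inj_seg[k]] += inj_traces[step, k]

        # --- Hines solve (parent-before-child ordering)
        for s in range(n_seg - 1, -1, -1):
            p = parent[s]
            if p >= 0:
                f = g_ax[s] / d[s]
                d[p] -= f * g_ax[s]
                r[p] += f * r[s]
        for s in range(n_seg):
            p = parent[s]
            if p < 0:
                v[s] = r[s] / d[s]
            else:
                v[s] = (r[s] + g_ax[s] * v[p]) / d[s]
            if not (abs(v[s]) <= 200.0):
                return (1, s, step, dip, gaba_rec, v_rec,
                        spike_cell[:n_spikes], spike_time[:n_spikes])

        # --- recordings at t + dt
        for k in range(dip_seg.shape[0]):
            s = dip_seg[k]
            dip[step + 1, dip_layer[k]] += (
                g_ax[s] * (v[parent[s]] - v[s]) * z_um[s] * 1e-6)
        for k in range(gaba_seg.shape[0]):
            s = gaba_seg[k]
            gaba_rec[step + 1, gaba_layer[k]] += (
                (sB[1, s] - sA[1, s]) * (v[s] - e_syn[1]))
        for k in range(n_rec):
            v_rec[step + 1, k] = v[rec_idx[k]]

        # --- somatic spike detection and recurrent delivery
        for c in range(n_cells):
            vs = v[soma_idx[c]]
            if (prev_soma[c] < spike_threshold and vs >= spike_threshold
                    and step - last_spike[c] > refractory_steps):
                if n_spikes < max_spikes:
                    spike_cell[n_spikes] = c
                    spike_time[n_spikes] = (step + 1) * dt
                    n_spikes += 1
                last_spike[c] = step
                dslot = (step + delay_steps) % delay_steps
                for j in range(conn_ptr[c], conn_ptr[c + 1]):
                    pend[conn_rec[j], dslot, conn_seg[j]] += conn_w[j]
            prev_soma[c] = vs

    return (0, -1, -1, dip, gaba_rec, v_rec,
            spike_cell[:n_spikes], spike_time[:n_spikes])


def exp2_peak_factor(tau_rise: float, tau_decay: float) -> float:
    """Normalization so a unit-weight event peaks at exactly 1 uS."""
    if not tau_decay > tau_rise > 0:
        raise ValueError("need decay_tau > rise_tau > 0")
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def run(assembled: dict, duration: float, dt: float = 0.025) -> dict:
    """Integrate an assembled network (see ``gammacd.network.Network.assemble``)
    for ``duration`` ms and return the raw recordings."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration / dt))
    if n_steps < 1 or abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be a positive multiple of dt")
    a = assembled
    n_seg = int(a["parent"].shape[0])
    v_init = a["v_init"]
    v = np.full(n_seg, float(v_init)) if np.isscalar(v_init) else np.array(v_init, float)
    gates = np.empty((11, n_seg))
    _init_gates(v, gates, a["ca_rest"])
    cai = np.full(n_seg, a["ca_rest"])

    cmdt = a["c_nF"] / dt
    d_static = cmdt + a["g_ax"] + a["child_gax_sum"]
    syn_tau = a["syn_tau"]  # shape (2, 2): rows AMPA/GABA, cols (rise, decay)
    syn_decay_r = np.empty((2, n_seg))
    syn_decay_d = np.empty((2, n_seg))
    syn_peak_factor = np.empty((2, n_seg))
    for rc in range(2):
        syn_decay_r[rc, :] = math.exp(-dt / syn_tau[rc, 0])
        syn_decay_d[rc, :] = math.exp(-dt / syn_tau[rc, 1])
        syn_peak_factor[rc, :] = exp2_peak_factor(syn_tau[rc, 0], syn_tau[rc, 1])
    # Optional per-segment override of AMPA kinetics (fast AMPA onto
    # fast-spiking interneuron segments).
    fast_tau = a.get("fast_ampa_tau")
    fast_seg = a.get("fast_ampa_seg")
    if fast_tau is not None and fast_seg is not None and np.any(fast_seg):
        syn_decay_r[0, fast_seg] = math.exp(-dt / fast_tau[0])
        syn_decay_d[0, fast_seg] = math.exp(-dt / fast_tau[1])
        syn_peak_factor[0, fast_seg] = exp2_peak_factor(fast_tau[0], fast_tau[1])
    # Explicit per-segment AMPA kinetics overrides (e.g. exogenous drive
    # synapses with their own time constants).
    ovr_seg = a.get("ampa_ovr_seg")
    ovr_tau = a.get("ampa_ovr_tau")
    if ovr_seg is not None and ovr_seg.size:
        for s, (tr, td) in zip(ovr_seg, ovr_tau):
            syn_decay_r[0, s] = math.exp(-dt / tr)
            syn_decay_d[0, s] = math.exp(-dt / td)
            syn_peak_factor[0, s] = exp2_peak_factor(tr, td)

    delay_steps = max(1, int(round(a["delay_ms"] / dt)))
    refractory_steps = int(round(1.0 / dt))
    ev_step = np.round(a["ev_time"] / dt).astype(np.int64)
    order = np.argsort(ev_step, kind="stable")
    inj_traces = np.ascontiguousarray(a["inj_traces"], dtype=float)
    if inj_traces.size and inj_traces.shape[0] < n_steps:
        raise ValueError("injected current traces shorter than the simulation")
    max_spikes = max(1000, int(a["soma_idx"].shape[0] * duration))

    (status, bad_seg, bad_step, dip, gaba, v_rec, spike_cell, spike_time) = _run(
        dt, n_steps,
        a["parent"], a["g_ax"], d_static, cmdt, a["area"],
        a["g_na"], a["g_k"], a["g_kdr"], a["g_km"], a["g_leak"],
        a["g_ca"], a["g_cat"], a["g_h"], a["g_kca"],
        a["e_na"], a["e_k"], a["e_ca"], a["e_h"], a["e_leak"],
        a["ca_tau"], a["ca_rest"], a["ca_drive_factor"],
        syn_decay_r, syn_decay_d, syn_peak_factor, a["e_syn"],
        a["soma_idx"], refractory_steps,
        a["conn_ptr"], a["conn_seg"], a["conn_w"], a["conn_rec"], delay_steps,
        ev_step[order], a["ev_seg"][order], a["ev_w"][order], a["ev_rec"][order],
        a["i_tonic"], a["inj_seg"], inj_traces,
        a["dip_seg"], a["dip_layer"], a["n_layers"], a["z_um"],
        a["gaba_seg"], a["gaba_layer"],
        a["rec_idx"], v, gates, cai,
        a["spike_threshold"], max_spikes)
    if status != 0:
        raise NumericalInstability(bad_seg, bad_step, dt)
    t = np.arange(n_steps + 1) * dt
    return {
        "t": t, "dipole": dip, "gaba_current": gaba, "v_rec": v_rec,
        "spike_cell": spike_cell, "spike_time": spike_time, "v_final": v,
    }
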