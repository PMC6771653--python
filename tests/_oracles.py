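"""Independent straight-line oracles used to cross-check the package.

These re-derive the governing relations directly (one expression at a time,
no shared code with the package) so the tests compare two separately coded
routes to the same physics.
"""

import math


def et0_oracle(tmin, tmax, rh_mean, rs, precip_unused, latitude, elevation, doy, u2=2.0):
    """Single-expression FAO56 Penman-Monteith chain for one day."""
    es0 = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
    es = (es0(tmax) + es0(tmin)) / 2.0
    ea = rh_mean / 100.0 * es
    vpd = max(es - ea, 0.0)
    t = (tmin + tmax) / 2.0
    delta = 4098.0 * es0(t) / (t + 237.3) ** 2
    gamma = 0.665e-3 * 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = math.acos(min(1.0, max(-1.0, -math.tan(phi) * math.tan(decl))))
    ra = max(24.0 * 60.0 / math.pi * 0.0820 * dr
             * (ws * math.sin(phi) * math.sin(decl)
                + math.cos(phi) * math.cos(decl) * math.sin(ws)), 0.0)
    rso = (0.75 + 2e-5 * elevation) * ra
    if rso <= 0:
        ratio = 1.0
    else:
        ratio = min(max(rs / rso, 0.25), 1.0)
    rnl = (4.903e-9 * 0.5 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4)
           * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * ratio - 0.35))
    rn = 0.77 * rs - rnl
    num = 0.408 * delta * rn + gamma * (900.0 / (t + 273.0)) * u2 * vpd
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(num / den, 0.0)


def et0_oracle_min_rh(tmin, tmax, rh_min, rs, latitude, elevation, doy, u2=2.0):
    """Same chain but taking actual vapour pressure from minimum humidity."""
    es0 = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
    es = (es0(tmax) + es0(tmin)) / 2.0
    ea = rh_min / 100.0 * es0(tmax)
    vpd = max(es - ea, 0.0)
    t = (tmin + tmax) / 2.0
    delta = 4098.0 * es0(t) / (t + 237.3) ** 2
    gamma = 0.665e-3 * 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = math.acos(min(1.0, max(-1.0, -math.tan(phi) * math.tan(decl))))
    ra = max(24.0 * 60.0 / math.pi * 0.0820 * dr
             * (ws * math.sin(phi) * math.sin(decl)
                + math.cos(phi) * math.cos(decl) * math.sin(ws)), 0.0)
    rso = (0.75 + 2e-5 * elevation) * ra
    ratio = 1.0 if rso <= 0 else min(max(rs / rso, 0.25), 1.0)
    rnl = (4.903e-9 * 0.5 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4)
           * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * ratio - 0.35))
    rn = 0.77 * rs - rnl
    num = 0.408 * delta * rn + gamma * (900.0 / (t + 273.0)) * u2 * vpd
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(num / den, 0.0)


def kc_ini_ode_oracle(et0, interval, tew, rew, dt=1e-4):
    """Brute-force integration of two-stage surface evaporation between
    wettings: energy-limited at 1.15*ET0 until REW is gone, then a falling
    rate proportional to the remaining evaporable fraction."""
    eso = 1.15 * et0
    de = 0.0
    t = 0.0
    while t < interval:
        rate = eso if de < rew else eso * (tew - de) / (tew - rew)
        de = min(de + rate * dt, tew)
        t += dt
    return de / (interval * et0)


def kc_curve_oracle(day, stages, kc_ini, kc_mid, kc_end):
    """Piecewise-linear crop coefficient, coded independently."""
    l1, l2, l3, l4 = stages
    if day <= l1:
        return kc_ini
    if day <= l1 + l2:
        return kc_ini + (kc_mid - kc_ini) * (day - l1) / l2
    if day <= l1 + l2 + l3:
        return kc_mid
    return kc_mid + (kc_end - kc_mid) * (day - l1 - l2 - l3) / l4


def step_day_oracle(prev_dr, prev_theta, prev_zr, zr, lai, et0, kc,
                    p, i, i_above, theta_wp, theta_fc, theta_sat,
                    p_tab, dr0_rel, beta=1.0, adjust_p=True):
    """One day of the depletion balance, re-derived from the governing
    relations: root growth carry, interception, wetness-scaled runoff,
    same-day drainage, stress-limited evapotranspiration."""
    awc = theta_fc - theta_wp
    dr = prev_dr + awc * max(zr - prev_zr, 0.0) * 1000.0 * dr0_rel
    etc = et0 * kc
    pf = min(max(p_tab + 0.04 * (5.0 - etc), 0.1), 0.8) if adjust_p else p_tab
    taw = awc * zr * 1000.0
    raw = pf * taw
    dr = min(dr, taw)
    ptot = p + i_above
    if lai > 0.0 and ptot > 0.0:
        cap = 0.25 * lai
        b = min(lai / 3.0, 1.0)
        int_total = cap * (1.0 - 1.0 / (1.0 + b * ptot / cap))
        int_p = int_total * p / ptot
        int_i = int_total * i_above / ptot
    else:
        int_total = int_p = int_i = 0.0
    surface = p + i - int_total
    rel = min(max((prev_theta - theta_wp) / (theta_sat - theta_wp), 0.0), 1.0)
    ro = min(surface * rel ** beta, surface)
    dri = dr - (p + i - ro - int_total)
    dp = max(-dri, 0.0)
    dri = max(dri, 0.0)
    ks = 1.0 if dri <= raw else min(max((taw - dri) / (taw - raw), 0.0), 1.0)
    eta = min(etc * ks, taw - dri)
    dr_new = min(dri + eta, taw)
    theta = theta_fc - dr_new / (zr * 1000.0)
    return dict(dr=dr_new, theta=theta, taw=taw, raw=raw, ks=ks, eta=eta,
                etc=etc, int_p=int_p, int_i=int_i, ro=ro, dp=dp)
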