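"""Deliberately naive day-by-day re-implementation of the tumor model.

Kept independent of the package internals (plain floats and lists, no
shared helpers) so it can serve as an oracle for the vectorized and
stateful implementations.
"""

from math import exp, log


def naive_trajectory(
    rho,
    t_half,
    k_hat,
    gamma_v,
    fractions,
    t_e,
    alpha_min=0.001,
    alpha_max=0.3,
    ab_tumor=10.0,
    ab_vasc=3.0,
    clearance="compound",
    mass_conserving=False,
):
    """Return (v_a list, v_n list, v_t list, k list) for days 0..t_e."""
    dose_of = dict(fractions)
    v_a, k = 100.0, float(k_hat)
    cohorts = []  # (creation_day, v0)
    vas, vns, vts, ks = [], [], [], []

    def vn_at(day):
        total = 0.0
        for t_i, v0 in cohorts:
            lag = day - t_i
            if clearance == "compound":
                expo = lag * (lag + 1) / 2.0
            else:
                expo = float(lag)
            total += v0 * 2.0 ** (-expo / t_half)
        return total

    for t in range(t_e + 1):
        vas.append(v_a)
        vns.append(vn_at(t))
        vts.append(v_a + vn_at(t))
        ks.append(k)
        if t == t_e:
            break
        d = dose_of.get(t, 0.0)
        po2 = 100.0 * (k - v_a) / k
        po2 = 0.0 if po2 < 0 else (100.0 if po2 > 100 else po2)
        alpha = alpha_min + po2 / 100.0 * (alpha_max - alpha_min)
        if d > 0:
            sf_t = exp(-alpha * 1.0 * d * (1 + d / ab_tumor))
            sf_v = exp(-alpha * gamma_v * d * (1 + d / ab_vasc))
        else:
            sf_t, sf_v = 1.0, 1.0
        factor = 1.0 + rho * log(k / v_a)
        if factor < 0:
            factor = 0.0
        grown = v_a * factor
        if d > 0:
            source = grown if mass_conserving else v_a
            cohorts.append((t, source * (1.0 - sf_t)))
        v_a = grown * sf_t
        k = k * sf_v
    return vas, vns, vts, ks
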