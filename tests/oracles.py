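"""Independent brute-force oracles for the test suite.

Everything here is reimplemented from the closed forms with plain ``math``
loops, deliberately not importing any aqpka computation code, so the tests
compare two independently written routes to the same quantity.
"""

import math

H = 6.62607015e-34
KB = 1.380649e-23
C_CM = 2.99792458e10
NA = 6.02214076e23
R = KB * NA


def mode_zpe(nu):
    return 0.5 * NA * H * C_CM * nu


def mode_u(nu, T):
    theta = H * C_CM * nu / KB
    return R * theta / (math.exp(theta / T) - 1.0)


def mode_s(nu, T):
    theta = H * C_CM * nu / KB
    x = theta / T
    return R * (x / (math.exp(x) - 1.0) - math.log(1.0 - math.exp(-x)))


def sackur_tetrode(mass_kg, T, P):
    q = (2.0 * math.pi * mass_kg * KB * T / H**2) ** 1.5 * KB * T / P
    return R * (math.log(q) + 2.5)


def rot_s_linear(i_mom, sigma, T):
    theta = H**2 / (8.0 * math.pi**2 * i_mom * KB)
    return R * (math.log(T / (sigma * theta)) + 1.0)


def rot_s_nonlinear(moments, sigma, T):
    thetas = [H**2 / (8.0 * math.pi**2 * m * KB) for m in moments]
    q = (math.sqrt(math.pi) / sigma) * math.sqrt(
        T**3 / (thetas[0] * thetas[1] * thetas[2])
    )
    return R * (math.log(q) + 1.5)


def free_rotor_s(nu, T, b_av):
    mu = H / (8.0 * math.pi**2 * C_CM * nu)
    mu_eff = mu * b_av / (mu + b_av)
    return R * (0.5 + 0.5 * math.log(8.0 * math.pi**3 * mu_eff * KB * T / H**2))


def gibbs_by_hand(e_elec, freqs, mass_kg, moments, linearity, sigma,
                  multiplicity, T, P, scheme="C0", nu0=100.0, b_av=1.0e-44,
                  zpe_scale=1.0):
    """Spreadsheet-style term-by-term Gibbs free energy (1 atm gas state)."""
    zpe = sum(mode_zpe(nu * zpe_scale) for nu in freqs)
    if scheme == "C1":
        work = [max(nu, nu0) for nu in freqs]
        u_vib = sum(mode_u(nu, T) for nu in work)
        s_vib = sum(mode_s(nu, T) for nu in work)
    elif scheme == "C2":
        u_vib = sum(mode_u(nu, T) for nu in freqs)
        s_vib = 0.0
        for nu in freqs:
            w = 1.0 / (1.0 + (nu0 / nu) ** 4)
            s_vib += w * mode_s(nu, T) + (1.0 - w) * free_rotor_s(nu, T, b_av)
    else:
        u_vib = sum(mode_u(nu, T) for nu in freqs)
        s_vib = sum(mode_s(nu, T) for nu in freqs)

    u_trans = 1.5 * R * T
    s_trans = sackur_tetrode(mass_kg, T, P)
    if linearity == "monatomic":
        u_rot, s_rot = 0.0, 0.0
    elif linearity == "linear":
        u_rot, s_rot = R * T, rot_s_linear(moments[2], sigma, T)
    else:
        u_rot, s_rot = 1.5 * R * T, rot_s_nonlinear(moments, sigma, T)
    s_elec = R * math.log(multiplicity)

    enthalpy = zpe + u_trans + u_rot + u_vib + R * T
    return e_elec + enthalpy - T * (s_trans + s_rot + s_vib + s_elec)


def ols_normal_equations(x, y):
    """Slope, intercept, r^2 via the explicit normal equations."""
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); sxy = sum(a * b for a, b in zip(x, y))
    syy = sum(v * v for v in y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    cov = n * sxy - sx * sy
    r2 = cov * cov / ((n * sxx - sx * sx) * (n * syy - sy * sy))
    return slope, intercept, r2


def rmse_brute(calc, exp):
    total = 0.0
    for c, e in zip(calc, exp):
        total += (c - e) ** 2
    return math.sqrt(total / len(calc))


def mean_std_brute(values, ddof=1):
    n = len(values)
    mean = sum(values) / n
    if n <= ddof:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - ddof)
    return mean, math.sqrt(var)
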