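"""Independent oracle: literal transcription of the published PC-SAFT
expressions for a pure fluid (hard chain + dispersion) and a brute-force
association sum for mixtures.

Deliberately written with explicit scalar loops and without sharing any code
with the package, so it can serve as a second, independent route in tests.
"""

import math

# universal model constants, rows i = 0..6: (a0i, a1i, a2i) and (b0i, b1i, b2i)
A_CONST = [
    (0.9105631445, -0.3084016918, -0.0906148351),
    (0.6361281449, 0.1860531159, 0.4527842806),
    (2.6861347891, -2.5030047259, 0.5962700728),
    (-26.547362491, 21.419793629, -1.7241829131),
    (97.759208784, -65.255885330, -4.1302112531),
    (-159.59154087, 83.318680481, 13.776631870),
    (91.297774084, -33.746922930, -8.6728470368),
]
B_CONST = [
    (0.7240946941, -0.5755498075, 0.0976883116),
    (2.2382791861, 0.6995095521, -0.2557574982),
    (-4.0025849485, 3.8925673390, -9.1558561530),
    (-21.003576815, -17.215471648, 20.642075974),
    (26.855641363, 192.67226447, -38.804430052),
    (206.55133841, -161.82646165, 93.626774077),
    (-355.60235612, -165.20769346, -29.666905585),
]


def hc_disp_pure(m, sigma, u, T, rho):
    """(a_hc, a_disp) for a pure chain fluid.

    rho is the number density in molecules/Angstrom^3.
    """
    d = sigma * (1.0 - 0.12 * math.exp(-3.0 * u / T))
    eta = math.pi / 6.0 * rho * m * d**3

    # hard-sphere term for a pure fluid (Carnahan-Starling)
    a_hs = (4.0 * eta - 3.0 * eta**2) / (1.0 - eta) ** 2
    g_hs = (1.0 - eta / 2.0) / (1.0 - eta) ** 3
    a_hc = m * a_hs - (m - 1.0) * math.log(g_hs)

    I1 = 0.0
    I2 = 0.0
    for i in range(7):
        a0i, a1i, a2i = A_CONST[i]
        b0i, b1i, b2i = B_CONST[i]
        ai = a0i + (m - 1.0) / m * a1i + (m - 1.0) / m * (m - 2.0) / m * a2i
        bi = b0i + (m - 1.0) / m * b1i + (m - 1.0) / m * (m - 2.0) / m * b2i
        I1 += ai * eta**i
        I2 += bi * eta**i
    C1 = 1.0 / (
        1.0
        + m * (8.0 * eta - 2.0 * eta**2) / (1.0 - eta) ** 4
        + (1.0 - m)
        * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
        / ((1.0 - eta) * (2.0 - eta)) ** 2
    )
    m2es3 = m * m * (u / T) * sigma**3
    m2e2s3 = m * m * (u / T) ** 2 * sigma**3
    a_disp = -2.0 * math.pi * rho * I1 * m2es3 - math.pi * rho * m * C1 * I2 * m2e2s3
    return a_hc, a_disp


def association_mixture(components, x, T, rho, n_iter=20000):
    """Brute-force 2B association term for a mixture.

    components: list of dicts with keys m, sigma, u, eps, kappa.
    Returns (a_assoc, XA, XB, max_mass_balance_residual).  Plain successive
    substitution from X = 1 without damping, run to stagnation.
    """
    n = len(components)
    d = [c["sigma"] * (1.0 - 0.12 * math.exp(-3.0 * c["u"] / T)) for c in components]
    z2 = math.pi / 6.0 * rho * sum(x[i] * components[i]["m"] * d[i] ** 2 for i in range(n))
    z3 = math.pi / 6.0 * rho * sum(x[i] * components[i]["m"] * d[i] ** 3 for i in range(n))
    om = 1.0 - z3

    delta = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            dij = d[i] * d[j] / (d[i] + d[j])
            g = 1.0 / om + dij * 3.0 * z2 / om**2 + dij**2 * 2.0 * z2**2 / om**3
            sij = 0.5 * (components[i]["sigma"] + components[j]["sigma"])
            epsij = 0.5 * (components[i]["eps"] + components[j]["eps"])
            kapij = math.sqrt(components[i]["kappa"] * components[j]["kappa"]) * (
                math.sqrt(components[i]["sigma"] * components[j]["sigma"]) / sij
            ) ** 3
            delta[i][j] = sij**3 * g * kapij * (math.exp(epsij / T) - 1.0)

    XA = [1.0] * n
    XB = [1.0] * n
    for _ in range(n_iter):
        XA_new = [
            1.0 / (1.0 + rho * sum(x[j] * XB[j] * delta[i][j] for j in range(n)))
            for i in range(n)
        ]
        XB_new = [
            1.0 / (1.0 + rho * sum(x[j] * XA[j] * delta[i][j] for j in range(n)))
            for i in range(n)
        ]
        moved = max(
            max(abs(a - b) for a, b in zip(XA_new, XA)),
            max(abs(a - b) for a, b in zip(XB_new, XB)),
        )
        # damped half-step, matching nothing in the package: simple average
        XA = [(a + b) / 2.0 for a, b in zip(XA, XA_new)]
        XB = [(a + b) / 2.0 for a, b in zip(XB, XB_new)]
        if moved < 1e-15:
            break
    resid = 0.0
    for i in range(n):
        fa = 1.0 / (1.0 + rho * sum(x[j] * XB[j] * delta[i][j] for j in range(n)))
        fb = 1.0 / (1.0 + rho * sum(x[j] * XA[j] * delta[i][j] for j in range(n)))
        resid = max(resid, abs(XA[i] - fa), abs(XB[i] - fb))
    a_assoc = sum(
        x[i]
        * (math.log(XA[i]) + math.log(XB[i]) - (XA[i] + XB[i]) / 2.0 + 1.0)
        for i in range(n)
    )
    return a_assoc, XA, XB, resid
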