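"""Independent reference implementations used only to check production code.

These are deliberately naive, straight-line transcriptions (pure Python,
no linear-algebra library) so they share no code path with the package.
"""

from __future__ import annotations


def gaussian_elimination(matrix, rhs):
    """Solve M x = b by Gaussian elimination with partial pivoting."""
    n = len(rhs)
    a = [list(map(float, row)) + [float(rhs[i])] for i, row in enumerate(matrix)]
    for col in range(n):
        pivot = max(range(col, n), key=lambda r: abs(a[r][col]))
        if abs(a[pivot][col]) < 1e-300:
            raise ZeroDivisionError("singular matrix")
        a[col], a[pivot] = a[pivot], a[col]
        for r in range(col + 1, n):
            f = a[r][col] / a[col][col]
            for c in range(col, n + 1):
                a[r][c] -= f * a[col][c]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        s = a[r][n] - sum(a[r][c] * x[c] for c in range(r + 1, n))
        x[r] = s / a[r][r]
    return x


def eem_system(coords, A, B, kappa, total_charge):
    """Assemble the EEM bordered system entry by entry (no vectorisation)."""
    n = len(A)
    m = [[0.0] * (n + 1) for _ in range(n + 1)]
    rhs = [0.0] * (n + 1)
    for i in range(n):
        for j in range(n):
            if i == j:
                m[i][j] = B[i]
            else:
                d = sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3)) ** 0.5
                m[i][j] = kappa / d
        m[i][n] = -1.0
        m[n][i] = 1.0
        rhs[i] = -A[i]
    rhs[n] = float(total_charge)
    return m, rhs


def peoe_two_atoms(params_a, params_b, cycles, h_like=(False, False)):
    """Hand transcription of the PEOE update for one A-B bond.

    params_* are (a, b, c) tuples; returns (q_a, q_b) after ``cycles``
    synchronous cycles with damping (1/2)^k, donor normalizer a+b+c
    (or 20.02 for hydrogen).
    """
    qa = qb = 0.0
    for k in range(1, cycles + 1):
        chi_a = params_a[0] + params_a[1] * qa + params_a[2] * qa * qa
        chi_b = params_b[0] + params_b[1] * qb + params_b[2] * qb * qb
        damp = 0.5 ** k
        if chi_b > chi_a:
            denom = 20.02 if h_like[0] else sum(params_a)
            t = (chi_b - chi_a) / denom * damp
            qa += t
            qb -= t
        elif chi_a > chi_b:
            denom = 20.02 if h_like[1] else sum(params_b)
            t = (chi_a - chi_b) / denom * damp
            qb += t
            qa -= t
    return qa, qb
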