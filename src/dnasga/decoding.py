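"""Single-error decoders for quaternary BCH codes, plus a brute-force oracle.

For designed distance 3 the classical Berlekamp–Massey machinery (and
its modified form for Galois-ring codes) collapses to closed-form
syndrome decoding: the error locator has degree at most 1, so the two
syndromes ``s1 = r(beta)`` and ``s2 = r(beta^2)`` determine the error
position and magnitude directly.  Both decoders honour the same
contract; :func:`berlekamp_massey` exposes the general field-case
locator computation for reference and cross-checking.

Positions in :class:`DecodeOutcome` are 0-based symbol indices in
sequence coordinates (index ``i`` holds the coefficient of
``x^(n-1-i)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .algebra import FieldContext, GF4_MUL, RingContext
from .codes import CodeSpec, as_symbol_vector, _poly_mod, syndromes

__all__ = [
    "DecodeOutcome",
    "decode_single_error",
    "brute_force_identify",
    "berlekamp_massey",
]

NO_ERROR = "no_error"
CORRECTED = "corrected"
FAILURE = "failure"


@dataclass(frozen=True)
class DecodeOutcome:
    """Result of attempting to move a vector onto the code.

    ``corrected`` implies the corrected vector is a codeword differing
    from the input at exactly ``position``; the input equals
    ``corrected + magnitude * x^(n-1-position)``.
    """

    status: str
    position: int | None = None
    magnitude: int | None = None
    corrected_vector: np.ndarray | None = None
    ambiguous: bool = False


def _subtract_error(vec: np.ndarray, pos: int, e: int, code: CodeSpec) -> np.ndarray:
    out = vec.copy()
    if code.symbol_domain == "Z4":
        out[pos] = (int(out[pos]) - e) % 4
    else:
        out[pos] = int(out[pos]) ^ e
    return out


def decode_single_error(r: Sequence[int] | np.ndarray, code: CodeSpec) -> DecodeOutcome:
    """Correct at most one symbol error via syndrome decoding.

    Field case (Berlekamp–Massey at t=1): with ``s1, s2`` nonzero,
    ``beta^j = s2 / s1`` locates the error and ``e = s1^2 / s2`` is its
    magnitude, accepted only if ``e`` is a nonzero GF(4) scalar with
    ``e * beta^j = s1``.

    Ring case (modified Berlekamp–Massey at t=1): if ``s1`` is a unit,
    ``s1 = e * xi^j`` for a unique unit magnitude ``e`` in {1, 3};
    if ``s1`` is a nonzero zero-divisor, ``s1 = 2 * xi^j`` locates the
    error through the mod-2 (Teichmüller) image with magnitude 2.
    Either way the decoder accepts only if ``s2 = e * beta^(2j)``.
    """
    vec = as_symbol_vector(r, code)
    s1, s2 = syndromes(vec, code)
    if s1.is_zero and s2.is_zero:
        return DecodeOutcome(status=NO_ERROR, corrected_vector=vec.copy())
    if s1.is_zero or s2.is_zero:
        return DecodeOutcome(status=FAILURE)

    ctx = code.context
    if code.kind == "field":
        assert isinstance(ctx, FieldContext)
        j = (ctx.log[s2.value] - ctx.log[s1.value]) % code.n
        # e = s1^2 / s2 must be a GF(4) scalar
        e_val = ctx.mul(ctx.mul(s1.value, s1.value), ctx.inv(s2.value))
        if e_val >> 2 or e_val == 0:
            return DecodeOutcome(status=FAILURE)
        if ctx.scale(e_val, ctx.alpha_pows[j]) != s1.value:
            return DecodeOutcome(status=FAILURE)
        j_exp, e = j, e_val
    else:
        assert isinstance(ctx, RingContext)
        hit = code.error_signatures.get(s1.coords)
        if hit is None:
            return DecodeOutcome(status=FAILURE)
        j_exp, e = hit
        expect_s2 = RingContext.scale(e, ctx.xi_pows[(2 * j_exp) % code.n])
        if s2.coords != expect_s2:
            return DecodeOutcome(status=FAILURE)

    pos = code.n - 1 - j_exp  # sequence coordinate of x^j
    corrected = _subtract_error(vec, pos, e, code)
    return DecodeOutcome(
        status=CORRECTED,
        position=pos,
        magnitude=e,
        corrected_vector=corrected,
    )


def brute_force_identify(r: Sequence[int] | np.ndarray, code: CodeSpec) -> DecodeOutcome:
    """Oracle: test ``r`` and all 3n single-symbol modifications.

    Membership is decided purely by polynomial divisibility
    (:func:`~dnasga.codes.is_codeword`'s route), independent of the
    syndrome decoder.  If several distance-1 codewords exist (impossible
    within the decoding radius of a distance-3 code) the lexicographically
    smallest ``(position, magnitude)`` is returned and the outcome is
    flagged ambiguous.
    """
    vec = as_symbol_vector(r, code)
    rem = _poly_mod(vec, code)  # ascending, length deg g
    if not rem.any():
        return DecodeOutcome(status=NO_ERROR, corrected_vector=vec.copy())

    X = code._x_pow_mod_g  # row j: ascending coeffs of x^j mod g
    hits: list[tuple[int, int]] = []  # (position, magnitude e with r = c + e x^j)
    for d in (1, 2, 3):
        if code.symbol_domain == "Z4":
            cand = (rem.astype(np.int16) + d * X.astype(np.int16)) % 4
            e = (-d) % 4  # r = c - d x^j
        else:
            cand = np.bitwise_xor(rem, GF4_MUL[d, X])
            e = d
        zero_rows = np.flatnonzero(~cand.any(axis=1))
        for j in zero_rows:
            hits.append((code.n - 1 - int(j), e))
    if not hits:
        return DecodeOutcome(status=FAILURE)
    hits.sort()
    pos, e = hits[0]
    corrected = _subtract_error(vec, pos, e, code)
    return DecodeOutcome(
        status=CORRECTED,
        position=pos,
        magnitude=e,
        corrected_vector=corrected,
        ambiguous=len(hits) > 1,
    )


def berlekamp_massey(code: CodeSpec, synd: Sequence) -> list:
    """General Berlekamp–Massey locator synthesis for field codes.

    Takes a sequence of syndrome :class:`~dnasga.algebra.FieldElement`
    values ``s1..s_2t`` and returns the error-locator polynomial
    ``sigma(x)`` as a list of field elements, constant term first.  At
    ``t = 1`` this reproduces the closed form used by
    :func:`decode_single_error`; it is retained for reference and
    cross-checked in the tests.
    """
    ctx = code.context
    if not isinstance(ctx, FieldContext):
        raise TypeError("berlekamp_massey applies to field codes")

    def fe(v: int):
        from .algebra import FieldElement

        return FieldElement(v, ctx)

    zero, one = fe(0), fe(1)
    sigma = [one]
    b = [one]
    L = 0
    mshift = 1
    delta_b = one
    for r_idx, s in enumerate(synd):
        # discrepancy
        d = s
        for i in range(1, L + 1):
            if i < len(sigma):
                d = d + sigma[i] * synd[r_idx - i]
        if d == zero:
            mshift += 1
            continue
        t_poly = list(sigma)
        coef = d * fe(ctx.inv(delta_b.value))
        shifted = [zero] * mshift + b
        width = max(len(sigma), len(shifted))
        new_sigma = []
        for i in range(width):
            si = sigma[i] if i < len(sigma) else zero
            bi = shifted[i] if i < len(shifted) else zero
            new_sigma.append(si + coef * bi)
        if 2 * L <= r_idx:
            L = r_idx + 1 - L
            b = t_poly
            delta_b = d
            mshift = 1
        else:
            mshift += 1
        sigma = new_sigma
    return sigma
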