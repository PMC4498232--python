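# Methods

## Model

The package decides membership of DNA sequences in quaternary cyclic
codes of designed distance 3 and, for sequences at Hamming distance 1
from a codeword, reconstructs the codeword ("code-generated sequence").
Two algebraic settings are supported.

**Galois ring codes.** Given a binary primitive polynomial f₂ of degree
m, the Graeffe lift h(y) = ±(e(y)² − y·d(y)²) mod 4, where
f₂(x) = e(x²) + x·d(x²), is the unique monic polynomial over Z4 with
h ≡ f₂ (mod 2) whose roots are Teichmüller elements; the sign is
negated exactly when deg f₂ is odd (the leading coefficient of
−y·d(y)² would otherwise be −1). GR(4, m) = Z4[x]/(h); the residue ξ of
x has multiplicative order n = 2^m − 1, which construction verifies by
generating the full power table (a non-primitive input is rejected).
Because the roots of h are ξ and its squaring conjugates ξ², ξ⁴, …, h
itself is the generator polynomial of an (n, n−m, 3) BCH code over Z4
with the consecutive roots ξ, ξ² required by the BCH bound.

**Galois field codes.** GF(4) is presented as {0, 1, a, b} with a a
root of x² + x + 1 and b = a + 1; internally a = 2, b = 3 and addition
is XOR. A degree-m primitive polynomial over GF(4) defines GF(4^m) with
primitive element α (order 4^m − 1, again verified exhaustively at
construction). The generator is minpoly(α)·minpoly(α²) over GF(4),
computed by multiplying linear factors over the extension and coercing
the coefficients down. All four field presets in the registry are
primitive under this fixed a/b presentation, so no alternative
assignment is needed.

**Registry.** The fifteen presets reproduce the published parameter
table verbatim (key, GI number, organism, labeling, ring/field flag,
primitive and generator polynomial strings). Construction validates
that the printed generator divides x^n − 1 (hard error otherwise) and
that it equals the derived generator — the Graeffe lift in the ring
case — warning on mismatch while keeping the printed polynomial as
ground truth. All fifteen printed generators match the derived ones
exactly. One row (preset `T4.a`) is flagged as a ring code in the
source table but carries a GF(4) primitive polynomial whose *field*
construction reproduces the printed generator exactly; the registry
therefore stores it as a field code and treats the flag as a
typographical slip.

## Conventions

* Symbol vectors: position i holds the coefficient of x^(n−1−i)
  (leftmost symbol = highest degree). Identification verdicts are
  invariant under cyclic shifts; only the reported coordinate moves.
* Error position j (exponent of x) maps to sequence coordinate
  n − 1 − j; all user-facing positions are 1-based, internal indices
  0-based.
* Polynomial strings use descending terms joined by `+`, coefficient 1
  omitted, `a`/`b` for the GF(4) generators; parsing and printing are
  mutually inverse and are the only serialization of algebra objects.
* Labelings A–D default to (A,C,G,T) → (0,1,2,3), (0,1,3,2), (0,2,1,3)
  and (0,2,3,1) respectively, with 2 ↔ a and 3 ↔ b for field codes.
  The published table names labelings A–D without defining the
  bijections, so these defaults are a convention of this package, not a
  claim about the original constructions; any permutation can be
  supplied programmatically.

## Decoding

With syndromes s₁ = r(β), s₂ = r(β²): both zero ⇒ codeword. Field
case: j = log(s₂/s₁) and e = s₁²/s₂, accepted iff e is a nonzero GF(4)
scalar and e·α^j = s₁ — the t = 1 specialization of Berlekamp–Massey
(a general BM synthesis is included for reference and cross-checked at
t = 1). Ring case (modified-BM role): a precomputed injective
signature table maps s₁ = e·ξ^j to (j, e) for e ∈ {1, 2, 3} — unit
magnitudes are distinguishable because −1 is not a Teichmüller element,
and the zero-divisor branch e = 2 is injective through the mod-2 image;
the decoder accepts iff s₂ = e·ξ^(2j). Anything else is `failure`
(distance ≥ 2). No such single-syndrome table exists in the field case:
GF(4)* is the order-3 subgroup of ⟨α⟩, so e·α^j collapses onto the
power table — the reason field decoding needs both syndromes for
location and the ring/field minimum-weight searches differ.

The brute-force oracle re-derives the same contract from divisibility
alone: it reduces r(x) mod g(x) once and tests all 3n single-symbol
modifications via a precomputed table of x^j mod g, returning the
lexicographically smallest (position, magnitude) hit and an ambiguity
flag. The flag is unreachable for inputs within distance 1 of a
codeword (balls of radius 1 are disjoint at distance 3); the tie-break
is fixed for determinism. The decoder and oracle are compared on mixed
input classes (codewords, distance 1, distance 2, uniform random) in
both the test suite and the acceptance script.

## Minimum-weight certificate

The designed distance is certified computationally rather than assumed:
weight-1 words are impossible since e·β^j ≠ 0; weight-2 words are
excluded by exhausting two-term patterns over the power tables (via the
signature table for rings, directly over supports for the n = 63 field
codes); an explicit weight-3 codeword is then found by bounded search
over supports {0, j, k} — sufficient by cyclicity — and re-verified by
polynomial divisibility. For the (1023, 1013, 3) code the search
completes in well under a second because each candidate third term is
resolved by table lookup instead of a quadratic scan.

## Codon annotation

Genetic codes are the NCBI translation tables via Biopython: standard
(1), vertebrate (2), yeast (3), mold/protozoan (4) and invertebrate (5)
mitochondrial, ciliate nuclear (6), plus Euplotid nuclear (10), which
carries the lineage-specific TGA→Cys reassignment — shipping the
standard table 10 was preferred over a hand-rolled custom table because
it is exactly that reassignment under an established identifier. For a
cloud verdict the codon containing the altered position is extracted
from the input and the code-generated sequence under a configurable
frame offset (default 0: sequence starts in-frame) and translated
under every table; `synonymous_under` is always computed, never
asserted, and effect classes (silent/missense/nonsense/stop-loss) are
derived per table. Alterations in an incomplete trailing codon are
reported as not translatable.

## Synthetic data

The fixture generator emulates the study conditions: coding sequences
whose length equals a code's block length and which differ from a
codeword in at most one nucleotide. It draws uniform random length-k
messages, encodes them non-systematically (m(x)·g(x) — sufficient since
messages are never transmitted, only membership matters), maps them
through a labeling and plants 0, 1 or 2 substitutions at recorded
positions, emitting FASTA plus a truth TSV. Output is byte-identical
for identical (spec, seed). What it does **not** emulate: real codon
usage, GC content, reading-frame structure or homology between records
— passing tests therefore demonstrate the correctness of the
identification machinery on in-model inputs, not that any natural gene
is a cloud member. Real sequences enter through FASTA exactly as
fixtures do.

## Problem sizes and numerical choices

The test suite runs exhaustive position × magnitude sweeps at n = 63
and sampled sweeps (≥ 500 draws) at n = 1023; the acceptance script
uses 1000 fixtures per 63-nt preset (14 000 identifications) and 1000
mixed decoder/oracle comparisons per preset (15 000), sizes at which
every check completes in seconds while covering every preset and both
decoder branches. All arithmetic is exact (small-integer tables mod 4
or XOR); there are no floating-point tolerances anywhere in the
computation. Strict length equality between sequence and code is
required by default; explicit `--pad trailing-A` / `--truncate tail`
policies exist for exploratory use and are logged loudly, since no
fitting rule for natural genes of non-code length is part of the
method.

## Known limitations

* Only designed distance 3 (single-error correction) is supported; no
  burst errors, erasures, list or Lee-metric decoding.
* The generator search space of the original constructions (choosing a
  code/labeling that identifies a given gene) is out of scope; the
  registry is a fixed table of known-good parameters.
* Homology searching, alignment and divergence-time analysis of
  code-generated sequences are downstream of this package and not
  implemented.
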