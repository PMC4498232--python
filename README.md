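# dnasga

Identify DNA coding sequences as codewords — or single-nucleotide
neighbours of codewords — of single-error-correcting BCH codes over
GF(4^m) and the Galois ring GR(4, m).

## The problem

A *G-linear code* reads a DNA sequence through a nucleotide labeling (a
bijection between {A, C, G, T} and the four symbols of Z4 or GF(4)) and
asks whether the resulting symbol vector belongs to a cyclic
error-correcting code. For the codes used here — BCH codes of designed
distance 3, i.e. (n, n−deg g, 3) codes with n = 63 or 1023 — a sequence
either **is** a codeword, or lies in the **cloud** of one (Hamming
distance exactly 1), or is unidentified. For a cloud sequence the
decoder emits the *code-generated sequence*: the unique nearest
codeword mapped back to nucleotides, together with the altered position
and the suggested base. Comparative analyses treat that suggested base
as a candidate plesiomorphic (ancestral) state, and the changed codon
is re-read under deviant genetic codes (mitochondrial and nuclear codon
reassignments such as TGA→Trp, AGA→Ser, ATA→Met, TGA→Cys), under which
a substitution that is non-synonymous in the standard code is often
synonymous.

## The codes

**Ring case.** A binary primitive polynomial f₂ of degree m is lifted
by the Graeffe (Hensel) construction — write f₂(x) = e(x²) + x·d(x²),
then h(y) = ±(e(y)² − y·d(y)²) mod 4 — to the basic irreducible h over
Z4. The Galois ring GR(4, m) = Z4[x]/(h) contains the Teichmüller unit
ξ (the residue of x) of order n = 2^m − 1, and h is the generator
polynomial g(x) of a (n, n−m, 3) BCH code over Z4 whose roots include ξ
and ξ². Example: f₂ = x⁶+x⁴+x³+x+1 lifts to g = x⁶+2x⁵+x⁴+x³+3x+1.

**Field case.** A primitive polynomial over GF(4) = {0, 1, a, b}
(b = a+1, a² = a+1) of degree m defines GF(4^m) with primitive element
α; g(x) is the product of the minimal polynomials of α and α² over
GF(4), giving a (4^m−1, 4^m−1−deg g, 3) code.

**Decoding.** With syndromes s₁ = r(β), s₂ = r(β²) (β = α or ξ), both
zero means codeword; a single error e·x^j gives s₁ = e·β^j,
s₂ = e·β^(2j), solved in closed form (the t = 1 specialization of the
Berlekamp–Massey and modified Berlekamp–Massey decoders; a zero-divisor
branch handles ring error magnitude e = 2 through the mod-2 Teichmüller
image). Every verdict can be cross-checked against a brute-force
oracle that tests all 3n + 1 single-symbol modifications for
divisibility by g(x).

Fifteen presets — one per analysed gene, fourteen (63, 57, 3) codes and
the (1023, 1013, 3) malate-dehydrogenase code — ship in a built-in
registry (`dnasga codes`).

## Worked example

Generate two synthetic 63-nt sequences, each one substitution away from
a random codeword of the preset `S02.b` (ring code, labeling B), then
identify and annotate them:

```sh
dnasga simulate --code S02.b --labeling B --n 2 --errors 1 --seed 11 \
    --out-fasta fixtures.fa --out-truth truth.tsv
dnasga annotate --input fixtures.fa --code S02.b --labeling B --out report.tsv
```

`report.tsv` (sequence column abridged):

```
seq_id           status position_1based ref_nt alt_nt ... before_codon after_codon aa_before aa_after effect_standard synonymous_under
S02.b_B_e1_0000  cloud  9               T      A      ... GGT          GGA         G         G        silent          standard,vertebrate-mito,...
S02.b_B_e1_0001  cloud  16              G      T      ... GTG          TTG         V         L        missense        .
```

Both records are in the cloud of a codeword: record one carries a T at
position 9 where the code-generated sequence has an A (a silent
GGT→GGA change, codon 3), record two a G at position 16 where the code
suggests T (a missense GTG→TTG, Val→Leu, synonymous under no shipped
table). `truth.tsv` confirms the planted positions (9 and 16) and bases
were recovered exactly.

The library mirrors the CLI: `build_code`, `identify`, `annotate`,
`min_weight_certificate`, `graeffe_lift`, etc. — see the module
docstrings.

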