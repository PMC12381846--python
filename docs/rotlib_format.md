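# The rotlib text dialect

`rotafit` writes rotamer libraries in the 2002-style backbone-dependent
library layout so that downstream packing software can consume them
directly. This document pins the dialect byte-for-byte.

## File layout

* One optional comment header line starting with `#`.
* One data line per well per backbone block.
* Blocks are ordered row-major over the backbone grid: `phi` outer,
  `psi` inner, each running `-180, -170, ..., 180` (37 values, **both
  endpoints present**, 10-degree step; 37 x 37 = 1369 blocks).
* Within a block, wells appear by **descending probability**.
* A backbone-independent library repeats the identical well list in every
  block; that repetition is what encodes backbone independence in a
  backbone-dependent file format.

## Data line

```
{code:>3s} {phi:5.0f} {psi:5.0f} {count:6d}  {r1} {r2} {r3} {r4}  {prob:.6f}{chi1:8.1f}{chi2:8.1f}{chi3:8.1f}{chi4:8.1f}{sd1:8.1f}{sd2:8.1f}{sd3:8.1f}{sd4:8.1f}
```

| field | meaning |
|---|---|
| `code` | three-letter residue code, right-justified |
| `phi`, `psi` | backbone bin centers in degrees |
| `count` | `round(probability * n_fitted_conformers)`; informational |
| `r1..r4` | 1-based per-chi rotamer bin indices (rank of the bin mean in ascending angle order); `0` for absent chi |
| `prob` | well probability, six decimals |
| `chi1..chi4` | per-chi well mean angles in degrees, one decimal; `0.0` for absent chi |
| `sd1..sd4` | per-chi well standard deviations in degrees, one decimal; `0.0` for absent chi |

Example line (two-chi residue, highest-probability well):

```
LEU  -180  -180    364  3 3 0 0  0.182203   179.9   179.9     0.0     0.0     2.3     2.4     0.0     0.0
```

A maximum of four chi angles is representable. Libraries for residues
with more rotatable torsions must be truncated to their first four chi
angles first (`truncate_to_four_chi`), which re-merges wells that become
indistinguishable and renormalizes probabilities.

## Reading

`read_rotlib` is whitespace-tolerant (it splits on runs of spaces rather
than fixed columns), skips `#` comment lines, and accepts files whose
blocks differ from one another — it then warns that the library is
backbone-dependent and returns the first block's wells.
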