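# rsaevol

Branch-wise comparison of amino-acid replacement rates and residue solvent
accessibility (RSA) change rates on fixed phylogenies.

Epistatic interactions inside a protein leave a footprint in how residues'
solvent exposure evolves: substitutions that move residues between buried
and exposed positions imply rearrangements of the globule, while
replacements that preserve exposure are structurally conservative.
`rsaevol` makes that comparison per inner tree branch.  It is written for
molecular evolution researchers who have a protein family alignment, a
fixed (e.g. species-constrained) tree topology, and per-residue RSA
predictions, and who want to know on which branches structural change ran
ahead of — or lagged behind — sequence change.

## The statistic

RSA values on the 5-unit grid −5..95 are recoded as a 20-letter
pseudo-amino-acid (PAA) alphabet (−5=A, 0=R, 5=N, ..., 85=Y, 90&95=V), so
both channels are ordinary alignments over 20 symbols.  Each channel gets
a family-specific GTR/REV model (exchangeabilities `s_ij`, frequencies
`pi`, rates `q_ij = s_ij pi_j` normalised to mean rate 1), estimated by
maximum likelihood on the fixed topology.  Branch lengths per channel are
fitted under a 3-class heterotachy mixture (every class carries its own
full branch-length set and frequency vector) or an edge-unlinked 8-category
site-diversity partition model.  Data variation comes from 100 delete-half
jackknife replicates of alignment columns, shared between channels.  For
every inner branch `b` and replicate, the statistic is

    ln L_b = ln( l_rsa(b) / l_aa(b) )

with both lengths floored at 5·10⁻⁵.  A branch's ln L sample is compared
against the pooled ln L values of the tree's inner branches (subsampled to
at most 10× the sample size) with a two-sided Mann–Whitney U test, Holm
correction within the tree, and Cliff's delta as effect size; branches
with near-zero RSA lengths or an ln L interquartile range ≥ 6 are filtered
first.  Calls: accelerated RSA evolution at delta ≥ 0.7 and Holm-adjusted
p < 10⁻⁴, decelerated at the mirrored condition, with an optional
consensus rule requiring partition-model agreement at delta ≥ 0.6.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

Simulate a six-taxon family in which one internal branch (`N2`) evolves
its RSA channel four times faster than its amino-acid channel, then run
the pipeline on the simulated files:

```sh
rsaevol simulate --out demo --n-taxa 6 --n-sites 2000 \
    --focal N2 --multiplier 4 --seed 7
rsaevol run --alignment demo/aa.fasta --rsa demo/rsa.tsv \
    --tree demo/tree.nwk --n-replicates 100 --seed 1 --outdir demo_out
```

which prints (about two minutes on one CPU, most of it REV estimation)

```
wrote aa.fasta, rsa.tsv, tree.nwk, truth.json to demo
4 inner branches, 1 called; outputs in demo_out
```

`demo_out/branch_comparisons.tsv` then contains one row per inner branch:

```
branch  n    median_lnL  iqr    p_holm    delta    call
N1      100   0.080      0.182  4.1e-02  -0.132    neutral
N2      100   1.285      0.287  4.4e-30   0.744    accelerated
N3      100   0.042      0.283  1.5e-04  -0.256    neutral
N4      100   0.005      0.112  1.0e-07  -0.357    neutral
```

The focal branch N2 sits at a median ln L of 1.29 ≈ ln 4 with Cliff's
delta near its ceiling and a vanishing Holm-adjusted p, while the other
branches stay near 0 and are neutral (a small p alone does not trigger a
call — the delta ≥ 0.7 gate must also pass).  `annotated_tree.nhx` tags
every inner branch with `accel|decel|neutral|filtered`, `rev_*.paml` hold
the estimated REV matrices, and `manifest.json` records every seed and
threshold so the run can be reproduced byte-for-byte.

The same operations are available as a library:

```python
import rsaevol as rv

aln  = rv.read_fasta("demo/aa.fasta")
tree = rv.read_newick("demo/tree.nwk", leaf_names=aln.taxon_names)
paa  = rv.encode_rsa20(rv.read_rsa_profile("demo/rsa.tsv", aln))
```

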