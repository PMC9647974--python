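# metahic

Meta-analytic Hi-C: aggregate many binned chromatin contact maps into a
high-depth "super-experiment", turn the result into gene–gene networks, and
measure how well chromatin contact frequency predicts gene function —
coexpression, eQTL target genes, and cross-species conservation.

## Who this is for

Hi-C contact maps are sparse, especially at long range and between
chromosomes (trans), because sequencing cost grows with the square of the
genome. Summing hundreds of independent experiments trades
condition-specificity for depth, and that depth converts directly into
power to detect functional long-range contacts. This package implements
the full analysis stack around that idea for anyone who wants to build,
normalize, and *evaluate* aggregated contact networks — plus a synthetic
generator with planted ground truth so every stage can be exercised and
validated at desk scale, without terabyte downloads.

## The model and metrics

A genome is divided into fixed-width bins (the *resolution*); a contact
matrix `C` counts read pairs spanning each bin pair, split into *cis*
(same chromosome) and *trans* entries. Matrices are entrywise-summed
(runs → project → meta), and each is KR-balanced separately in cis and
trans: find `d > 0` with

    (diag(d) · C · diag(d)) · 1 = 1

over the in-mode entries (Knight–Ruiz iteration, Sinkhorn–Knopp fallback).
The gene network sets `W(g,h) = max over bins of g × bins of h of C`, and
edges are rank-standardized to (0, 1].

Every evaluation is the same neighbor-ranking task, scored as a
Mann–Whitney AUROC with mid-rank ties. For entity *e* with candidate set
*S*, scores *x* and binary labels *y*:

    AUC(e) = ( Σ_{i: y_i=1} rank(x_i) − n₊(n₊+1)/2 ) / (n₊ · n₋)

* **contact coexpression** — per gene, Hi-C edge weights predict the
  gene's top-1% coexpression partners; report the mean AUC over genes.
* **compartment / subcompartment / TAD coexpression** — same labels,
  scored by the fraction of experiments in which the gene pair shares a
  structural unit (A/B compartments from PCA of the observed/expected
  correlation matrix, gene-density oriented; TADs from a simplified
  TopDom-style caller).
* **contact-eQTL / proximity-eQTL** — per variant, contact frequency
  (or inverse variant–TSS distance) predicts the significant eGene among
  same-chromosome genes in unique 1-kb bins.
* **contact conservation** — per 1:1-ortholog gene, one species' ranked
  contacts predict the other species' top-10% contacts, averaged over
  both directions; **contact-coexpression conservation** predicts the
  other species' top-1% coexpression one-directionally.

A score of 1 means the ranking retrieves the labels perfectly, 0.5 is
chance, 0 is perfect reversal.

## Worked example

```python
import metahic as mh

cfg = mh.SimulationConfig(seed=1)          # 3 x 2 Mb chromosomes, 10-kb bins, 200 genes
ds = mh.simulate_dataset(cfg)              # contacts + expression + eQTLs + truth

d = mh.depth(ds.contacts)
print(f"depth: cis={d.cis_depth:.0f} trans={d.trans_depth:.0f}")

cis, trans = mh.split_cis_trans(ds.contacts)
balanced = mh.aggregate([mh.kr_balance(cis, "cis"), mh.kr_balance(trans, "trans")])

hic = mh.rank_standardize(mh.contact_network(balanced, ds.genes))
coexp = mh.coexpression_network([ds.expression])

res = mh.contact_coexpression(hic, coexp, fraction=0.01)
print(f"contact coexpression: mean AUC={res.mean_auc:.3f} "
      f"median={res.median_auc:.3f} over {res.n_scored} genes")

r_c = mh.contact_eqtl(ds.contacts, ds.genes, ds.eqtls)
r_p = mh.proximity_eqtl(ds.genes, ds.eqtls, ds.genome)
print(f"contact-eQTL mean AUC={r_c.mean_auc:.3f} vs proximity-eQTL={r_p.mean_auc:.3f} "
      f"({r_c.n_scored} variants)")
```

prints

```
depth: cis=840772 trans=159228
contact coexpression: mean AUC=0.607 median=0.598 over 200 genes
contact-eQTL mean AUC=1.000 vs proximity-eQTL=0.946 (47 variants)
```

The simulated dataset plants expression–contact coupling (κ = 0.6), so
contact weights retrieve coexpression partners well above chance; the
planted eQTL variants sit in bins whose contact with their true eGene is
boosted, so contact ranks the eGene first for every scored variant while
linear proximity does not.

The same pipeline is scriptable from the shell: `metahic simulate`,
`aggregate`, `balance`, `depth`, `gene-net`, `coexpr-net`,
`compartments`, `tads`, `coexpr-auc`, `unit-auc`, `eqtl-auc`,
`conserve`, `gene-vector`, and `run` (the end-to-end recipe). See
`metahic --help`.

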