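# Methods

## Mutual Rank

For genes *a*, *b* with expression vectors over the same samples, the
package computes the Pearson correlation `PCC(a, b)` (undefined, and marked
as such, when either vector has zero variance; at least 3 samples are
required). For each gene, all other rankable genes are ordered by
descending PCC; `rank_a(b)` is the position of *b* in *a*'s ordering
(1 = best correlate) and

```
MR(a, b) = sqrt(rank_a(b) · rank_b(a)).
```

MR is symmetric, bounded by `min(rank_ab, rank_ba) ≤ MR ≤ max(rank_ab,
rank_ba)` and by `1 ≤ MR ≤ G − 1` for a universe of G rankable genes, and
invariant under per-gene affine rescaling of the expression values (so
FPKM vs TPM vs logged units only matter through their effect on PCC
itself; the matrix is otherwise treated opaquely).

Numerical choices:

* **Ties** in PCC receive average (fractional) ranks. This is
  deterministic and order-independent; it is also why MR values such as
  √(2 · 1.5) appear in the presence of duplicated or perfectly collinear
  genes.
* **Zero-variance genes** are excluded from every profile and every rank
  universe (logged once per run). A zero-variance reference or compound
  aggregate is an error raised before any MR is computed.
* **Self pairs** have no MR; tables carry an explicit `self` marker row
  for the reference, never a 0 or 1.
* Candidate ordering and table sorting break exact ties by gene ID so
  repeated runs are byte-identical.

## The targeted trade-off

The full G × G MR matrix is impractical for large transcriptomes on a
workstation, so the targeted workflow restricts MR computation to the *N*
genes with the highest **signed** PCC to the reference (default N = 200;
requests above 1,000 are clamped with a warning; strong negative
correlates are deliberately never candidates). The directional ranks are
nonetheless always taken over the **full** rankable universe. This is the
single most consequential design decision in the package: with
full-universe ranks, every MR in the targeted table is identical to the
corresponding entry of the exhaustive all-pairs MR matrix, which the test
suite enforces against an independent brute-force oracle (complete
`np.corrcoef` matrix, per-row ranking) at 1e−9 on matrices up to 50 genes,
including engineered bit-exact ties.

Reference modes:

* **single** — one reference gene.
* **set** — all-pairs MR among a gene list; list members missing from the
  matrix (or unrankable) are dropped with a warning, and fewer than two
  survivors is an error. The tabular view is keyed to the first retained
  gene and preserves input order.
* **compound** — a synthetic row appended as the per-sample `average`,
  `sum`, `maximum` or `minimum` of a gene set, then analysed exactly like a
  single reference. The compound row joins every gene's rank universe.
  Because ranks are scale-invariant, `sum` and `average` give identical
  tables.

## Supporting-information integration

Descriptions, symbols, fold changes (passed through untransformed — the
tool treats them as display data), Pfam domains and GO terms are joined
onto the table by exact, case-sensitive gene ID after whitespace trimming;
genes absent from a map get empty cells, and annotation never drops or
reorders rows. Custom categories (named sets of gene IDs, Pfam domains or
GO terms) each add one column flagging `Y` when the gene is a member or
carries at least one member attribute. GO-kind categories match **direct**
assignments by default; an opt-in `propagate` flag extends each gene's
terms with their ontology ancestors (is_a and part_of, transitively).
Propagation defaults off because flat assignment files are the common
input and silent ancestor inflation would overstate category membership.

## GO enrichment

The foreground is every table gene with MR **strictly** below the cutoff
(default 100) plus the reference. The background universe N is the set of
matrix genes carrying at least one non-obsolete GO assignment — not all
matrix genes — so k/n/K/N stay mutually consistent. Each term annotated on
at least one foreground gene is scored with the exact upper-tail
hypergeometric probability P(X ≥ k) (SciPy's survival function, which the
tests pin to rational-arithmetic tail summation at 1e−12 for N ≤ 500).
All three GO namespaces are tested and adjusted together.
Benjamini–Hochberg FDR is the default adjustment; Bonferroni–Holm is
selectable — both are first-class because both conventions are common in
published enrichment tables. Alt IDs resolve to their primary term;
obsolete terms stay loadable but never enter enrichment.

## Network and heatmap

Edges connect pairs with MR **strictly** below the threshold (default 100
for top-200-style tables; 10 is the customary choice when visualising a
dozen genes); isolated vertices are retained so missing edges are visible.
Vertex attributes carry symbols, category flags and fold changes; exports
are GraphML and a gene_a/gene_b/mr TSV. The heatmap is a long-format
symmetric grid in input order — no clustering, so reference-set order is
preserved — with diagonal `self` markers; optional raster rendering maps
low MR to high intensity. In the single-reference workflow the
heatmap/network are built from the pairwise MR matrix over the reference
plus the top `graph_genes` table rows (default 12, a practical size for a
readable network figure).

## Synthetic data

The generator plants equicorrelated modules: member gene *i* of a module
with target correlation ρ is `sqrt(ρ)·latent + sqrt(1−ρ)·noise_i` with one
shared standard-normal latent per module and independent unit-normal
noise, giving expected within-module sample PCC = ρ (exactly 1 at ρ = 1);
background genes are pure independent noise. Defaults used throughout the
tests: 1,000 genes × 30 samples, 10-gene modules at ρ = 0.9 — a module
size, cohesion and atlas size typical of a well-coregulated biosynthetic
pathway in a medium-sized expression atlas. The companion supporting-file
generator plants each module's GO term on its members (plus sparse random
background terms at 10% per gene over 5 terms), a shared Pfam domain and
elevated fold changes (uniform 4–8 vs ≈1) for module 1, symbols for module
members only, a toy ontology covering every emitted term, and one
gene-list category per module.

What this emulates — and what it does not: the generator reproduces the
*correlation structure* coregulation leaves in an expression matrix, which
is the only property MR consumes. It does not model RNA-seq count
distributions, library-size effects, correlated background pathways or
shared regulators between modules. Passing recovery tests therefore show
the pipeline faithfully turns correlation structure into low MRs and
enrichment signals; they do not certify performance on any particular real
atlas, where background genes are themselves co-regulated and dataset
choice strongly shapes MR neighbourhoods.

A property of MR worth knowing when interpreting recovery simulations
under this i.i.d.-noise background: a background gene whose own best
correlate happens to be the reference earns `rank_ba ≈ 1` and hence
MR ≈ sqrt((m+1)·1) for a module of size m, which can undercut the weakest
module member (whose MR can reach m because co-members compete for each
other's top ranks). Such reciprocal interlopers are genuine low-MR pairs,
not artifacts; in simulations they appear in most runs, so module members
reliably fill the lowest-PCC positions and the lowest ~2m MR rows rather
than the exact m−1 lowest MRs.

## Defaults at a glance

| parameter | default | meaning |
| --- | --- | --- |
| `top_n` | 200 (max 1,000) | candidate-list size, highest signed PCC to the reference |
| `mr_threshold` | 100 | strict cutoff for network edges and the enrichment foreground |
| `adjust` | `benjamini_hochberg` | p-value adjustment (`holm` selectable) |
| `propagate` | off | GO ancestor propagation for categories and enrichment |
| `graph_genes` | 12 | top table rows entering the single-mode heatmap/network |
| fixtures | 1,000 × 30, modules 10 @ ρ=0.9 | synthetic study conditions |

## Limitations

* Pearson correlation only; no Spearman or biweight midcorrelation.
* No genome-wide all-pairs MR precomputation, by design.
* No expression normalisation, batch correction or DE testing — those
  arrive precomputed.
* No GO-Slim projection and no parent–child decorrelated enrichment tests.
* Gene ID matching is exact (case-sensitive, trimmed); no identifier
  mapping layer.
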