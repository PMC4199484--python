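# likfill

Likelihood-weighted gene annotation scoring and MILP gap filling for
genome-scale metabolic models.

`likfill` turns protein-homology evidence (BLAST tabular hits against a
high-confidence reference) into per-gene annotation likelihoods, propagates
them through a biochemistry template (annotation → role → complex → reaction)
into reaction likelihoods with assembled Boolean gene rules, and uses those
likelihoods as objective weights in mixed-integer gap filling of draft
metabolic models. It also ships flux balance / variability analysis,
iterative gap filling with sensitivity-based pruning, knockout and
single-substrate phenotype simulation, and a seeded synthetic-fixture
generator so that the whole pipeline runs end-to-end with no external data.

## The scoring chain

1. **Log-scores.** Every hit with E ≤ 1e-5 scores `S = -log10(E + k)`,
   `k = 1e-200` (caps S at 200 for reported E = 0).
2. **Annotation likelihoods.** For gene *i* with best score `S_max`:

   `p(i∈A_a) = Σ_{j∈A_a} S_ij² / (PC·S_max + Σ_j S_ij²)`, `PC = 40`.

   The pseudocount calibrates a lone hit at E = 1e-40 to exactly 50%.
   Squaring keeps many weak hits from dominating; each gene's likelihoods
   sum to strictly less than 1.
3. **Roles.** Per-gene role likelihood is the sum of that gene's annotation
   likelihoods mapping to the role; the organism-level value is the max over
   genes, and genes within 80% of the max are retained, OR-linked.
4. **Complexes.** Minimum over member roles; subunit gene sets AND-linked.
5. **Reactions.** Maximum over catalyzing complexes; complexes within 80% of
   the max are retained, OR-linked, forming the reaction's candidate rule.

## Gap-filling costs

Candidates are universal-database reactions (either direction) and
reversibility relaxations of existing irreversible reactions. With
`C(x) = 1 - p(x)`:

```
base(x)       = 1 + 25·[transporter] + 5·[low-confidence source]
U(x, dir)     = (12 + 2·max(ΔG opposing dir, 0)) / 10   (1.2 if ΔG unknown)
parsimony:      λ = base(x)        + U·[dir unfavorable]
likelihood:     λ = C(x)·base(x)   + U·[dir unfavorable]
reversal:       12 · U(x, new dir) / 1.2                (both modes)
```

The thermodynamic surcharge and reversal costs are deliberately *not*
likelihood-scaled. **Note:** the exact published weighting equation is not
reproducible from prose alone; this additive form is reconstructed from the
stated constraints (likelihoods rescale only addition costs; the two
calibration anchors are U = 1.2 at low/unknown ΔG and U = 3.2 at
ΔG = 10 kcal/mol).

The MILP minimizes Σ λ·z subject to steady state over the merged network,
media uptake limits, and a minimum target flux of 1e-5, with a doubling
time-limit schedule capped at 86400 s. Each gated flux uses an integer
companion variable (`v ≤ y ≤ M·z`) so that solver integrality tolerances
cannot leak flux through unselected candidates.

## CLI

```bash
likfill fixtures --seed 1 --out-dir fx/           # synthetic test universe
likfill likelihoods --blast fx/blast.tsv --reference fx/reference.tsv \
    --annotation-roles fx/annotation_to_role.tsv \
    --complex-roles fx/complex_roles.tsv \
    --complex-reactions fx/complex_reactions.tsv --out lik.tsv
likfill gapfill --model draft.json --universal fx/universal.json \
    --media complete --mode likelihood --likelihoods lik.tsv \
    --out sol.json --out-model filled.json
likfill iterate --model draft.json --universal fx/universal.json \
    --media complete --mode likelihood --likelihoods lik.tsv \
    --prune --out model_out.json --report report.json
likfill simulate --model fx/gold.json --phenotypes fx/phenotypes.tsv \
    --media-dir fx/ --out phen.json
likfill workflow targeted-likelihood --model draft.json \
    --universal fx/universal.json --likelihoods lik.tsv \
    --minimal-media fx/media_glucose_minimal.tsv --out-dir out/
```

Exit codes: 0 success, 2 usage, 3 infeasible, 4 timeout, 5 validation.

## File formats

- **Models**: a JSON dialect (schema documented in
  `likfill/model_core.py`) or SBML Level 3 with fbc flux bounds and gene
  associations. Attributes SBML cannot carry (ΔG, transporter flag, source
  confidence, priority class) live in a sidecar TSV `<model>.attrs.tsv`
  with header `reaction_id, delta_g, is_transporter, source_confidence,
  priority_class`.
- **Media TSV**: `compound_id, max_uptake`. The `simulate` command discovers
  media files named `media_<name>.tsv` in `--media-dir`.
- **BLAST hits**: tabular TSV — headered (`qseqid`, `sseqid`, `evalue`
  columns), headerless outfmt-6 (12 columns), or plain 3-column.
- **Reference TSV**: `gene_id, annotation` (one annotation per gene).
- **Template TSVs**: `annotation_to_role(annotation, role)`,
  `complex_roles(complex, role)`, `complex_reactions(complex, reaction)`.
- **Likelihood TSV**: `reaction_id, likelihood, gpr`.
- **Phenotype TSV**: `kind, key, media_name, observed_growth`.

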