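# homeocaps

Classification of **homeolog loss** and **gene silencing** in allopolyploid
plants from CAPS (cleaved amplified polymorphic sequence) assays, with
cDNA-AFLP fragment scoring and a ground-truthed study simulator.

## The problem

A recently formed allotetraploid such as *Tragopogon mirus*
(= *T. dubius* × *T. porrifolius*) carries two homeologous copies of every
gene, one per parental genome. Two fates are of interest soon after
polyploid formation:

* **homeolog loss** — one parental copy is physically gone from the genome;
* **silencing** — the copy is present in genomic DNA but its transcript is
  absent.

A CAPS assay separates the two. For each locus, a restriction enzyme is
chosen whose cut pattern differs between the parental alleles, so each
parent shows at least one *diagnostic* gel band the other lacks. A polyploid
individual whose genomic amplicon shows both parents' diagnostic bands is
**additive**; missing one parent's diagnostics indicates **loss** of that
homeolog. Running the same assay on cDNA and contrasting it with the genomic
call distinguishes true silencing (genomic additive, transcript band absent)
from loss-driven absence (the gene is simply gone). cDNA-only methods such
as cDNA-AFLP cannot make that distinction — which is exactly why this
package refuses to emit a silencing call without a genomic-tier result.

At the study level the package tallies, over *g* informative genes
(2*g* homeologs assayed), the per-parent loss percentages
100·(genes with loss of that parent's homeolog)/2*g*, the combined loss
percentage, and the silencing percentage over surveyed genes — the standard
summary statistics of this study design.

## What is in the package

| module | role |
| --- | --- |
| `homeocaps.sequence_model` | IUPAC DNA types, FASTA/TSV readers, reverse complement |
| `homeocaps.digest` | in-silico restriction digestion, gel-band model, diagnostic assay design |
| `homeocaps.genotyping` | genomic-tier calls (additive / loss / ambiguous / unscorable), parental-polymorphism screen, sequencing confirmation of losses |
| `homeocaps.expression` | cDNA-tier calls (silencing vs loss-driven absence), band-intensity dominance ratio |
| `homeocaps.aflp` | cDNA-AFLP presence/absence classification (monomorphic / novel / maternal- / paternal-origin) |
| `homeocaps.stats` | study tallies, per-parent percentages, per-population breakdown |
| `homeocaps.simulate` | ground-truthed synthetic studies and deterministic tally fixtures |
| `homeocaps.pipeline`, `homeocaps.cli` | end-to-end orchestration and the `homeocaps` command |

## Worked example

Simulate a small study (12 loci, 20 tetraploids over seven populations, a
2%/1% paternal/maternal per-individual per-locus loss rate) and run the full
pipeline on the files it writes:

```sh
python - <<'EOF'
from homeocaps.simulate import SimulationConfig, simulate_cohort
cfg = SimulationConfig(seed=7, n_loci=12, n_polyploids=20,
                       loss_prob_paternal=0.02, loss_prob_maternal=0.01,
                       silencing_prob=0.01, parental_polymorphism_prob=0.05,
                       band_dropout_prob=0.0, size_jitter_rel=0.0)
simulate_cohort(cfg).write("demo")
EOF
homeocaps run-all --alleles demo/alleles.fasta --enzymes demo/enzymes.tsv \
    --observations demo/observations.tsv --individuals demo/individuals.tsv \
    --out demo/reports
```

`demo/reports/summary.json` then contains (abridged):

```json
{
  "genes_surveyed": 10,
  "genes_additive": 7,
  "genes_with_loss": 3,
  "genes_excluded": 0,
  "homeologs_assayed": 20,
  "paternal_loss_percent": 10.0,
  "maternal_loss_percent": 10.0,
  "combined_loss_percent": 20.0,
  "genes_with_silencing": 4,
  "individuals_with_loss": 3
}
```

Ten of the 12 simulated loci had an informative enzyme in the bundled panel
and were surveyed; loss of a parental homeolog was detected at 3 genes
(2 paternal, 2 maternal — one gene lost each parent in different
individuals), i.e. 2/20 = 10.0% of assayed homeologs per parent;
4 genes showed at least one silenced individual. `demo/reports/genotypes.tsv`
and `expression.tsv` carry the per-individual × locus calls with the
diagnostic bands supporting each one.

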