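# hexaw

Hexamer-spectrum irregularity indices for protein-coding sequences.

`hexaw` quantifies how unevenly 6-base words occur in the coding sequences
(CDS) of a genome.  Uneven hexamer usage is a fingerprint of triplet
periodicity and longer-range codon correlations, and an inverse proxy for the
algorithmic (Kolmogorov) complexity of coding DNA: the more repetitive and
biased the sequence, the larger the index.  It is aimed at comparative
genomics users who want a single, ranking-based number per genome (or per CDS
collection) that can be compared across bacteria, plants, metazoa and
viruses.

## The statistic

For a CDS set, every 6-base word starting at in-frame positions 1, 4, 7, …
(3-base step) increments one cell of a 4096-cell array U.  The array is
normalised to a total of 10⁶ and sorted ascending — the same ranking used for
Gini-coefficient curves — giving the observed spectrum Q₁.  Two Monte Carlo
nulls are built by re-shuffling each CDS 100 times and averaging before
ranking:

* **R₁** — bases permuted at random, with no stop codon created in frame;
* **T₁** — codons permuted at random (codon usage conserved exactly).

Q₁ and a null are stacked into a 2×4096 table and compared with the
mutual-information statistic

    I = Σ m ln m − Σ x ln x − Σ y ln y + L ln L        (nats, L = 2×10⁶)

whose doubled value is the G statistic of the table (≈ χ²).  Fisher's
square-root normal approximation gives the reported index

    W = √(4I) − √(2·df − 1),        df = 4095.

**W₁** (Q₁ vs R₁) responds to triplet periodicity plus all longer
correlations; **W₂** (Q₁ vs T₁) only to correlations of six bases and longer.
Identical spectra give the floor W = −√8189 ≈ −90.49.  Bacterial genomes
split into two groups by W₁ (boundary configurable, default 475).

## Worked example

Generate a synthetic CDS set with moderate adjacent-codon coupling and
analyse it:

```
$ hexaw synth --n-cds 40 --length 900 --seed 2 --coupling 0.5 --out demo.fa
wrote 40 sequences of 900 nt to demo.fa

$ hexaw analyze --cds demo.fa --replicates 50 --seed 1
demo    n_cds=40    n_windows=11960    W1=1248.96    W2=1200.09    group=2
```

All 40 records were retained and contributed 11 960 hexamer windows.
W₁ ≈ 1249 says the ranked hexamer spectrum is far more uneven than stop-free
base shuffling can explain; W₂ ≈ 1200 says most of that structure spans six
bases or more — as it must here, since the generator's coupling makes
adjacent codons repeat and codon shuffling cannot erase that.  (Indices from
small synthetic sets sit on an inflated scale relative to genome-size sets;
see `docs/methods.md` on the 10⁶/Sum noise term.)  `group=2` applies the
default W₁ ≥ 475 boundary.

For real data, point `--cds` at an Ensembl-style CDS FASTA export (one
organism per file); `hexaw batch --manifest sets.tsv` (columns
`label<TAB>path`) writes one report row per genome plus an optional
`--scatter` file of (W₂, W₁) pairs for population plots.  Q₁/R₁/T₁ curves
can be dumped as rank–value TSVs with `--dump-spectra`.

The same functionality is available as a library:

```python
from hexaw import PipelineConfig, analyze_cds_set
report = analyze_cds_set("demo.fa", PipelineConfig(replicates=100, seed=1))
print(report.W1, report.W2, report.group)
```

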