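# pollenifc

Analysis of label-free **impedance flow cytometry (IFC)** measurements of
pollen viability and sterility, built around the hazelnut (*Corylus
avellana*) phenotyping workflow: event simulation, polygon gating,
viability/sterility quantification, hydration mode tracking, univariate
sterility clustering, and a dye-exclusion microscopy validation arm.

## The problem

In IFC, pollen grains cross a microfluidic channel under an AC field and
each transit is recorded as a complex impedance — an amplitude |Z| = √(Zr² +
Zi²) and a phase θ = atan2(Zi, Zr) per measurement frequency.  At ~2 MHz
the amplitude tracks grain volume; at ~8 MHz the phase reports membrane
integrity.  On a phase–amplitude scatter plot pollen separates into three
populations: **viable** (high phase), **dead** (lower phase — compromised
membranes), and **sterile** (low amplitude — small, anomalous grains with
no cytoplasmic content that heat inactivation does not affect).  Gating
these populations yields per-sample viability and sterility percentages;
across a cultivar panel, clustering the per-genotype average sterility
separates translocation-type semi-sterile genotypes (~50 % sterile pollen)
from genotypes producing good pollen.

The package is for researchers who want a reproducible, scriptable version
of this analysis: every stage runs on plain CSV event tables and JSON gate
files, and a seeded synthetic-event generator stands in for instrument
exports so the full pipeline is testable end to end.

## Worked example: panel sterility clustering

The packaged reference panel carries the average sterility/viability of 35
hazelnut genotypes (33 cultivated + 2 wild, with two extra orchard samples:
37 rows).  Cluster its sterility column:

```sh
$ pollenifc cluster --k 5 --seed 1 --out clusters.csv
k-means k=5 cluster means: [3.86, 13.65, 43.59, 54.1, 73.58]
hierarchical k=2 cluster means: [6.66, 48.09]
```

Reading the output: exact (dynamic-programming) univariate k-means at
k = 5 groups the genotypes at mean sterilities of 3.9 %, 13.6 %, 43.6 %,
54.1 % and 73.6 % — the last "cluster" being the single extreme cultivar
Tonda di Giffoni — while hierarchical clustering cut at k = 2 splits the
panel into a 14-genotype low-sterility group (6.7 %) and a 23-genotype
high-sterility group (48.1 %), the signature expected from heterozygous
reciprocal translocations producing ~50 % unbalanced gametes.  The
companion `clusters_curves.csv` holds the BIC/n, gap and silhouette curves
behind the cluster-count choices (gap and silhouette select k = 2; BIC/n
selects k = 5 on the averages).

The same pieces are available as a library:

```python
from pollenifc import clustering

panel = clustering.load_reference_panel()
km = clustering.ckmeans_1d(panel["sterility_mean"], 5)
gap = clustering.gap_statistic(panel["sterility_mean"], k_max=6, b=100, seed=1)
print(km.means.round(2), gap.k)   # [ 3.86 13.65 43.59 54.1  73.58] 2
```

## Simulated experiments

Every experimental design in the study can be generated synthetically and
pushed through the analysis:

```sh
pollenifc simulate --preset mixing    --seed 7 --out mixing.csv    # heat-inactivation validation
pollenifc simulate --preset hydration --seed 7 --out course.csv    # 0–7 h pre-hydration course
pollenifc simulate --preset panel     --seed 7 --out panel.csv     # 37-genotype screening panel
pollenifc gate     --input mixing.csv --out gates.json             # automatic gate derivation
pollenifc quantify --input mixing.csv --gates gates.json --out stats.csv
pollenifc hydration --input course.csv --out series.csv            # KDE mode tracking
pollenifc report   --input panel.csv --out panel_report.csv        # full panel pipeline
```

The hydration analysis tracks the kernel-density global modes of the dead
and viable phase distributions per time step: the dead mode drifts from
192° at 0 min to 188° after ~5.5 h while the viable mode stays at 198°, so
the population separation grows from ~6° to ~10° and measured viability is
maximal (and most trustworthy) after ~6 h of pre-hydration.

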