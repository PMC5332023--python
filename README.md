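# hyladelim

Integrative species delimitation for hylid treefrog complexes.

Widespread Amazonian treefrogs routinely turn out to be complexes of
several cryptic species. The standard integrative workflow for splitting
them combines three independent character sets — mitochondrial sequence
divergence, advertisement-call structure, and morphometrics — and then
assesses the conservation status of each resulting candidate. `hyladelim`
implements that workflow end to end as a tested, scriptable pipeline for
the *Dendropsophus leucophyllatus–triangulum* complex and datasets shaped
like it. It is aimed at systematists and bioacousticians who have an
aligned 16S matrix, a folder of WAV recordings, a specimen table, and
occurrence coordinates, and want reproducible tables instead of manual
spreadsheet work.

## The method

**Genetic screening.** Pairwise uncorrected p-distances
*p = mismatches / compared sites* are computed on the alignment under
pairwise deletion of gaps and ambiguity codes, then aggregated to
mean ± SD (range) within and between named mtDNA clades. Divergence is
binned (low < 3%, moderate 3–5%, high > 5%, very high > 7%) and clades are
grouped by single linkage: clades joined by a chain of inter-clade means
≤ 3% form one candidate lineage. Analyst overrides (e.g. keeping a clade
whose low distance rests on a short sequence fragment) are explicit,
logged inputs.

**Bioacoustics.** Calls in this complex consist of a long pulsed trill
(Type I note), optionally followed by short Type II notes; pure Type II
series are aggressive calls. From each mono WAV the package extracts the
13 standard call parameters (durations, pulse counts, rise times,
inter-note and inter-pulse distances, dominant frequency averaged over the
beginning/middle/end of the call, and bandwidth) via the analytic-signal
envelope, peak-picking, gap-based note segmentation, and a 1024-point Hann
spectrogram (43.1 Hz resolution at 44.1 kHz). Five Type I variables per
male enter a correlation-matrix PCA; components with eigenvalue > 1 are
retained and groups are compared with Welch t-tests on the scores.

**Morphometrics.** Snout–vent-length tables are summarised per clade and
compared with Welch's unequal-variance t-test, computable directly from
printed summary statistics: *t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂)* with
Welch–Satterthwaite degrees of freedom.

**Evidence integration.** Each genetically distinct group becomes a
Confirmed Candidate Species (CCS) when acoustic *or* morphological
evidence is independently diagnostic, an Unconfirmed Candidate Species
(UCS) when both are unavailable, and a Deep Conspecific Lineage (DCL) when
evidence is available but not diagnostic.

**Conservation.** Extent of occurrence is the minimum convex polygon of
the occurrence points, with area evaluated on the WGS84 authalic sphere;
a degraded-habitat fraction and a minimal, advisory Red List suggestion
(IUCN criterion B1's 20,000 km² bound) complete the range report.

Because the original recordings and sequences were never deposited, the
package ships a synthetic-data module that generates every input with
known statistical structure: Jukes–Cantor alignments on a star topology
(expected p-distance ¾(1−e^(−4d/3)) is analytic), raised-cosine pulsed
calls, normal SVL samples, and occurrence clouds.

## Worked example

```python
from hyladelim import datasets
from hyladelim.delimit import apply_overrides, cluster_lineages, integrate_evidence
from hyladelim.stats import welch_from_summary

means = datasets.clade_distance_means()          # published 16S clade means
part = cluster_lineages(means, threshold=0.03)
print(len(part), part)
part, log = apply_overrides(part, [datasets.clade_f_override()])
result = integrate_evidence(part, datasets.evidence_table())
print(len(part), result.counts())

svl = datasets.svl_male_summaries().set_index("clade")
t, df, p = welch_from_summary(26.0, 0.9, 8, 23.8, 1.5, 185)
print(f"t = {t:.2f}, df = {df:.0f}, p = {p:.5f}")
```

prints

```
8 (('A',), ('B',), ('C',), ('D',), ('E',), ('F', 'H'), ('G',), ('I',))
9 {'CCS': 5, 'UCS': 4}
t = 6.53, df = 9, p = 0.00012
```

At the 3% threshold only clades F and H merge (their mean distance, 2.5%,
is an artifact of a short 16S fragment); the documented override restores
nine candidate lineages, of which five are confirmed by call or
morphological evidence and four remain unconfirmed. The Welch test shows
clade I males (26.0 ± 0.9 mm, n = 8) are significantly larger than clade C
males (23.8 ± 1.5 mm, n = 185).

A full synthetic study can be generated and analysed from the shell:

```bash
hyladelim simulate --seed 1 --out study/
hyladelim distances --alignment study/alignment.fasta \
    --clade-map study/clade_map.tsv --out study/gd/
hyladelim delimit --summary study/gd/clade_summary.tsv \
    --evidence study/evidence.tsv --split-out "F:short 16S fragment" \
    --out study/dl/
```

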