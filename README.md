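# freqconn

Frequency-specific functional connectivity networks from ROI time series.

Resting-state hemodynamic signals couple brain regions at multiple
timescales. `freqconn` resolves that coupling by frequency: it estimates
magnitude-squared coherence between all ROI pairs, averages it within
narrow overlapping bands, builds density-matched binary networks per band,
and asks how the *topology* differs across bands — how cleanly the network
separates into communities (segregation, measured by modularity Q), how
short its paths are (integration, measured by global efficiency E), and
which nodes act as hubs or form a rich club. It is a library for
researchers analysing multi-subject ROI panels (fMRI or optical imaging),
with a synthetic-cohort generator that provides ground truth for every
stage.

## The model in brief

For signals x, y the coherence at frequency f is

    C_xy(f) = |P_xy(f)|² / (P_xx(f) P_yy(f)),

Welch-estimated and averaged within bands (default grid: 0.01–0.25 Hz, 23
half-overlapping 0.02 Hz bands). A band's coherence matrix is thresholded
at sparsity S — keeping the ⌊S·n(n−1)/2⌋ strongest pairs — so every
network has exactly the same edge count and metric differences reflect
wiring patterns. Subjects aggregate through two consensus matrices:
Ce (fraction of subjects exhibiting each edge → thresholded to the group
network) and Ca (fraction of subjects co-assigning each ROI pair →
community-detected for the group partition). Communities come from seeded
multistart Louvain; partitions are compared with normalized mutual
information (NMI) against degree-preserving network nulls; hubs are nodes
≥ 1 SD above the mean in both degree and eigenvector centrality; the
rich-club coefficient Φ(k) = 2E_k/(N_k(N_k−1)) is tested per degree k
against rewired nulls; and band contrasts in Q and E use paired t-tests
with Benjamini–Yekutieli FDR over the sparsity × metric grid.

The package ships an 87-ROI parcellation table (three functional systems:
default mode, fronto-parietal and cingulo-opercular task control, with MNI
coordinates and per-band community assignments) used throughout the
examples and tests.

## Worked example

```python
import freqconn as fc

table = fc.load_roi_table()
vlf = table["community_vlf"].to_numpy()
lf = table["community_lf"].to_numpy()
systems = table["system"].to_numpy()
print(f"NMI(VLF, LF)      = {fc.nmi(vlf, lf):.2f}")
print(f"NMI(VLF, systems) = {fc.nmi(vlf, systems):.2f}")
print(f"NMI(LF, systems)  = {fc.nmi(lf, systems):.2f}")
```

prints

```
NMI(VLF, LF)      = 0.59
NMI(VLF, systems) = 0.33
NMI(LF, systems)  = 0.32
```

— the two band-specific community assignments of the packaged parcellation
agree strongly with each other (NMI 0.59; 1 would be identical partitions)
and each agrees moderately (0.33 / 0.32) with the a-priori functional
systems, i.e. both bands organize into communities resembling the known
systems while differing in detail.

Running the full pipeline on a synthetic 28-subject cohort at the default
study conditions (`examples/05_band_comparison.py`):

```
    metric  sparsity         t        p  significant
...
modularity      0.25  4.644768 0.000079         True

modularity is higher in the lower band (flagged in 4/5 cells);
efficiency is flagged in 0/5 cells ...
```

— the band with discrete planted communities is measurably more segregated
(higher Q) at matched density, while integration capacity (E) does not
differ: the planted regime the generator encodes.

The `examples/` directory walks through each capability: the parcellation
similarity values (01), band-resolved coherence curves (02), group network
and consensus community construction (03), hub and rich-club detection
(04), and the band-wise statistical comparison (05). A thin command-line
interface mirrors the stages (`freqconn simulate | spectra | build |
community | hubs | compare`).

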