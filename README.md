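# ieegnet

Sampling-bias-aware functional network analysis for intracranial EEG.

Brain networks estimated from intracranial EEG depend strongly on how the
electrodes were implanted. Electrocorticography (ECoG) covers the cortical
surface with grids and strips plus a few depth electrodes; stereo EEG (SEEG)
uses only stereotactically placed depth shafts. The two strategies sample the
same brain very differently, and network models built on one do not transfer
cleanly to the other. `ieegnet` is a pipeline for quantifying and correcting
that sampling bias in interictal functional networks of epilepsy surgery
patients, aimed at researchers building network models to localize the
epileptogenic zone.

## What it computes

Per patient, from a multichannel interictal recording:

1. **Connectivity.** The recording is cut into 1-second windows; each window
   yields a symmetric adjacency matrix by multitaper magnitude-squared
   coherence in the beta (15–25 Hz) or low-gamma (30–40 Hz) band, or by
   broadband cross-correlation (5–115 Hz bandpass, 60 Hz notch, maximum
   absolute normalized cross-correlation over ±100 ms lags). The patient's
   network is the entrywise **median over windows**, restricted to
   grey-matter contacts.
2. **Node strength and distinguishability.** Node strength is
   *s<sub>i</sub>* = Σ<sub>j</sub> *A<sub>ij</sub>*. The resection-zone
   distinguishability **D<sub>rs</sub>** is the normalized Mann–Whitney
   U statistic (equivalently the ROC area) separating resected from spared
   node strengths: 1 when every resected node is weaker than every spared
   node, 0 when uniformly stronger, 0.5 when strength carries no information.
   Ties get midrank (half) credit.
3. **Sampling-bias corrections.** Three network modifications, composed in
   order:
   - **DC** — distance correction: a rational polynomial
     *w(d)* = (*p*₁*d* + *p*₂)/(*d* + *q*₁) is fit per modality and edge
     class (surface–surface, surface–depth, depth–depth), pooling edges
     across patients, and each edge is residualized;
   - **UL** — unilateral restriction to the hemisphere containing the
     resection;
   - **AR** — atlas reduction to one node per ROI, averaging inter-ROI edges.
4. **Graph structure.** Louvain modularity maximization (signed extension
   for distance-corrected residual networks) and the participation
   coefficient *P<sub>i</sub>* = 1 − Σ<sub>s</sub>(κ<sub>is</sub>/k<sub>i</sub>)².
5. **Cohort statistics.** Rank-sum comparisons of D<sub>rs</sub> between
   modalities per condition, sign-rank of each corrected condition against
   the uncorrected network, Fisher's exact test for categorical cohort
   tables, and the Pearson correlation between AR-condition D<sub>rs</sub>
   and surgical focality (number of resected atlas ROIs).

Because matched patient data cannot ship with a package, `ieegnet` includes a
first-class **synthetic cohort generator**: toy ECoG/SEEG implant geometries
with a 24-region synthetic atlas, planted ground-truth connectivity (distance
decay per edge class, elevated depth–depth coupling, community structure,
resection effects), and multichannel recordings whose band coherence realizes
the planted network. Every stage of the pipeline is tested against this known
truth.

## Worked example

```python
import ieegnet as ig
from ieegnet.network import build_patient_network
from ieegnet.conditions import run_conditions, cohort_report, conditions_frame

spec = ig.CohortSpec(n_ecog=8, n_seeg=8, duration=120.0)
patients = ig.generate_cohort(spec, seed=42)
nets = [build_patient_network(p.sensors,
                              ig.connectivity_matrix(p.recording, "beta_coherence"),
                              p.modality, patient_id=p.patient_id)
        for p in patients]
fits = ig.fit_class_models(nets, seed=42)
sets = [run_conditions(net, fits) for net in nets]
print(conditions_frame(sets).groupby(["modality", "condition"])["drs"].median())
report = cohort_report(sets)
```

prints

```
modality  condition
ECoG      AR           0.000
          DC           0.049
          GM           0.028
          UL           0.063
SEEG      AR           0.926
          DC           0.843
          GM           0.574
          UL           0.839
GM rank-sum ECoG vs SEEG: p = 0.0002 (medians 0.028 vs 0.574)
focality: rho = -0.731, p = 0.0013, n = 16
```

Read: in this synthetic cohort the planted effects reproduce the
modality gap — resected tissue looks *strong* in ECoG (D<sub>rs</sub> ≪ 0.5,
because broad cortical resections remove well-connected tissue and the
mesial depth contacts they include are intrinsically high-coherence) and
*weak* in SEEG (D<sub>rs</sub> > 0.5, focal ablation targets are
hypo-connected) — and the negative correlation between D<sub>rs</sub> and
the number of resected ROIs: the more focal the surgery, the weaker the
removed tissue relative to the rest of the network.

The fitted distance curves are available in `fits`, e.g. the SEEG
depth–depth profile `w(d) = (0.406 d + 17.73) / (d + 25.45)` (RMSE 0.024
over 32 807 pooled edges).

The same pipeline runs from the shell:

```bash
ieegnet simulate --seed 42 --out cohort/           # sensor CSVs, truth CSVs, EDFs
ieegnet run-all --config config.yaml --out results/
```

Real recordings enter as EDF plus a contact metadata CSV (columns:
`contact_id,x,y,z,electrode_type,tissue,roi_label,hemisphere,resected`), or
as precomputed adjacency CSVs; `ieegnet validate` checks inputs first.

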