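# hadasl

Hadamard time-encoded pCASL perfusion analysis: encoding-scheme design,
general-kinetic-model simulation, decoding, voxelwise CBF/ATT
quantification with partial volume correction, and test-retest
reliability statistics — driven end to end by a synthetic digital-phantom
cohort so every stage is verifiable without scanner data.

## Who this is for

Groups running (or planning) multi-delay arterial spin labeling studies
who want to understand and validate the time-encoded variant: how the
sub-bolus timing is designed, how decoding recovers one perfusion-weighted
image per delay, how CBF and ATT are fitted, and what test-retest
reliability (wsCV) and between-scanner reproducibility (ICC) to expect
from a two-session design.

## The model

A seven-block labeling train is played with label/control states following
the columns of a pruned 8×7 Sylvester Hadamard matrix. Block *i* (play
order, longest first) has duration τᵢ and effective post-labeling delay

    PLDᵢ = PLD_base + Σ_{j>i} τⱼ

— for the reference scheme (PLD_base = 500 ms, τ =
1175/683/482/374/305/257/224 ms) this gives PLDs of
2825/2142/1660/1286/981/724/500 ms. Durations are T1-compensated: each
block delivers the same signal `(1 − e^{−τ/T1b}) e^{−PLD/T1b}` despite the
longer decay of early blocks.

The decoded signal per sub-bolus follows the general kinetic model
(plug-flow bolus, arrival at the arterial transit time Δt, blood decay T1b
before arrival, apparent tissue decay T1′ after):

    ΔM(t) = 2 M0a f α T1′ e^{−Δt/T1b} (1 − e^{−(t−Δt)/T1′}),  Δt ≤ t < Δt+τ

(zero before arrival, exponential tail after the bolus). CBF `f` and ATT
`Δt` are estimated per voxel by penalized least squares with an ATT prior
(mean 1.3 s, SD 0.3 s, weight tied to the noise level), the flow profiled
out in closed form over a dense ATT grid. Reliability is summarized by the
within-subject coefficient of variation, `100·√(mean((x₁−x₂)²/2 /
((x₁+x₂)/2)²))`, and reproducibility by two-way mixed single-measures ICC
with 95% CI.

See `docs/methods.md` for the full model description, the synthetic-cohort
design, and known limitations.

## Worked example

Design the scheme and run a small synthetic replication:

```
$ hadasl design-scheme --total 3.5
base_pld_s: 0.5
block_durations_s:
- 1.1834283291178207
- 0.6820527490058184
- 0.48115466406706814
- 0.3720622289027289
- 0.30340910068973115
- 0.2561879662915208
- 0.22170496192531
...
# effective PLDs (ms): 2817 2135 1653 1281 978 722 500
```

The designed durations land within ~1% of the reference timing. Background
suppression for the 4 s preparation window:

```
$ hadasl design-bs --prep 4.0 --t1 1.3 --t1 0.9 --t1 4.3
pulse times (s): 2.0789 3.4677
T1=1.30 s -> residual Mz +0.0822
T1=0.90 s -> residual Mz +0.1178
T1=4.30 s -> residual Mz +0.1178
```

Two inversions leave all three tissue compartments within 2 percentage
points of the +10% residual target. A full two-scanner cohort, in Python:

```python
from hadasl import ReplicationConfig, replicate

res = replicate(ReplicationConfig(dims=(24, 24, 12), master_seed=1000))
print(res.reliability.query("roi == 'gray_matter'"))
```

```
        roi scanner metric  wscv_percent   n
gray_matter     mmr    cbf          3.45  26
gray_matter     mmr    att          1.10  26
gray_matter   skyra    cbf          2.69  26
gray_matter   skyra    att          0.82  26
```

Gray matter CBF test-retest variability sits at 2.7–3.5% and ATT at ~1% —
ATT is the more reliable parameter, the ordering the in-vivo literature
reports for this sequence family. The same result object carries the
between-scanner reproducibility (`res.reproducibility`: GM ICC ≈ 0.94
here), the scanner/age/gender GLM (`res.glm`: the injected +50 ms scanner
ATT offset is detected at p ≈ 2e-4), the negative ATT–CBF correlation
(`res.correlations`: GM r ≈ −0.40), and the GM/WM contrasts
(`res.contrasts`: CBF ratio ≈ 2.53). `hadasl replicate --out results/`
writes the same tables plus NIfTI maps and a manifest to disk.

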