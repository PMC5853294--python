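# tagflux

Carbon-flux accounting for triacylglycerol (TAG) biosynthesis from
radiolabel pulse-chase experiments, built around the nitrogen-deprivation
response of green microalgae such as *Dunaliella tertiolecta*.

Under N deprivation these algae first pile assimilated CO₂ into starch and
only then, after a ~12–24 h lag, accumulate TAG — raising the question of
where TAG carbon actually comes from. `tagflux` implements the accounting
that answers it from ¹⁴C pulse-chase data:

* **Unit conversions** — scintillation counts (dpm per 10⁶ cells) to carbon
  amounts via the tracer's specific activity
  (nmol C = 1000 · dpm / SA), and carbon to pool mass via fixed carbon
  weight fractions (starch 40%, TAG 80%):
  m<sub>starch</sub> [µg] = n<sub>C</sub> [nmol] · M<sub>C</sub> · 10⁻³ / 0.40.
* **Pathway partition** — daily TAG synthesis is split into three routes
  and closed against the measured total:
  * *from starch*: ¹⁴C appearing in TAG **after** the end of each daily
    bicarbonate pulse (carbon that passed through a storage pool);
  * *de novo direct*: TAG label already present at each pulse's label end;
  * *de novo via polar lipids*: the convolution
    via-PL(d) = Σ<sub>s&lt;d</sub> PL<sub>synth</sub>(s) · f(d−s),
    where f(·) are per-day PL→TAG transfer fractions estimated from an
    acyl-tracer (¹⁴C-palmitate) chase.
  Budget closure checks Σ calculated ≈ Σ measured.
* **Transfer fractions and efficiencies** — e.g. the chase estimator
  ΔTAG / Δ(starch+soluble), and the fraction of pre-formed polar-lipid
  label handed to TAG.
* **Compartmental simulator** — a linear, piecewise-constant pulse-chase
  model dx/dt = A(t)·x with a clamped external tracer pool, a
  photosynthesis-decay gate on uptake and a TAG-onset lag. It generates
  all six labeling designs (total labeling, day-1 pulse chase, daily
  bicarbonate and palmitate pulses, day-1 and pre-N acyl chases) so every
  analysis stage is testable without wet-lab data.
* **Model fitting** — weighted least-squares estimation of transfer rate
  constants with multi-start optimization and a replicate bootstrap,
  linking the arithmetic estimators to first-order kinetics.

## Worked example

```python
import tagflux as tf

ds = tf.generate_paperlike_dataset(seed=1)        # six designs, CV 10%, n=3
part = tf.partition_from_dataset(ds)
print(tf.render_partition_report(part))
print(tf.pathway_fractions(part).round(3).to_string())
```

```
Day  Starch    De novo direct  De novo via PLs  Total calculated  Total measured
1    0.0       8.3             0.0              8.3               15.0
2    32.0      3.7             11.6             47.4              54.0
3    36.6      1.0             13.0             50.6              42.4
...
Total 279.0    17.8            85.8             382.6             366.0

from_starch       0.729
de_novo_direct    0.047
de_novo_via_pl    0.224
```

Reading: on this synthetic run about 73% of the TAG carbon accumulated over
eight days of N deprivation came from the storage route, ~22% moved through
newly made polar lipids, and ~5% was fixed and esterified the same day; the
calculated 8-day total (382.6 nmol C per 10⁶ cells) agrees with the
independently measured accumulation (366.0) to within ~5%. Day 1 is
attributed to direct synthesis only, so its calculated value undershoots
the measured one by design.

The same pipeline is exposed on the command line:

```bash
tagflux all --config run.yaml --out results/     # simulate -> partition -> fit
tagflux report --input results/partition.tsv
```

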