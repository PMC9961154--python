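# zebratrack

Quantitative behavioral phenotyping for adult zebrafish, plus a circadian
gene-set module for the accompanying brain RNA-seq design.

Zebrafish behavioral batteries score anxiety, aggression and sociality from
video-tracked 2-D trajectories: the **novel tank test** (bottom-dwelling and
freezing as anxiety indicators), the **mirror biting test** (entries into and
time within a contact strip and approach area near a mirror), the **social
preference test** (time in the conspecific vs. empty half of a chamber), the
**shoaling test** (group cohesion, shoal polygon area, excursions,
polarization), and a **day–night locomotor assay** (activity reversal).
`zebratrack` implements the full endpoint computation for these assays from
calibrated trajectory tables, together with seeded synthetic generators that
produce trajectories with known ground truth, so every endpoint can be
validated against planted behavior. A companion module implements the
circadian gene-set workflow for a genotype × time-of-day (2 × 2) RNA-seq
design: FPKM, the expressed-gene filter, DEG thresholds, contrast set
algebra, and the G-test of enrichment.

## Core definitions

With positions $p_i \in \mathbb{R}^2$ (cm) sampled at 25 fps:

- **Speed classes** — large $v > 15$ cm/s, moderate $1 \le v \le 15$, small
  $0 \le v < 1$; **freezing** is speed $< 0.5$ cm/s sustained $\ge 1$ s and
  overrides "small".
- **Zone endpoints** — entries (outside→inside transitions), time in zone
  (frames inside / fps), distance in zone, latency to first entry. Zones are
  half-open distance bands (top/bottom split at 5 cm; mirror contact
  $[0, 1.5)$ cm, approach $[1.5, 5)$ cm; CS/ES split at the chamber
  midline).
- **Social preference value** —
  $(t_{CS} - t_{ES}) / (t_{CS} + t_{ES}) \in [-1, 1]$.
- **Shoal geometry** — mean/nearest/farthest pairwise distances; shoal
  polygon area = convex hull of fish centroids; shoal present iff some
  subset of ≥ 3 fish has all pairwise distances < 12 cm; excursion iff some
  fish is > 12 cm from its nearest neighbor; **polarization**
  $\phi = \lVert \tfrac1n \sum_i \hat{h}_i \rVert$, the polar order
  parameter of unit headings.
- **G-test** — $G = 2\sum O \ln(O/E)$ on the 2 × 2 expressed-gene table
  (circadian × mutation-affected), $p$ from $\chi^2_1$.
- **Condition factor** — $100 \, W / L^3$ (g, cm).

## Worked example

Simulate a 5-minute novel-tank session for an unbiased swimmer and a
bottom-biased (anxiety-like) one, then score the standard endpoints:

```python
from zebratrack.simulate import FishStateModel, simulate_fish
from zebratrack.trajectory import arena_preset, zone_preset
from zebratrack.zones import zone_occupancy
from zebratrack.ethogram import summarize_ethogram

tank, zones = arena_preset("novel_tank"), zone_preset("novel_tank")
for label, bias in [("unbiased", 0.0), ("bottom-biased", 4.0)]:
    model = FishStateModel.default(bottom_bias=bias)
    traj, _ = simulate_fish(model, tank, duration=300, seed=42)
    top = zone_occupancy(traj, zones, "top")
    eth = summarize_ethogram(traj)
    print(f"{label}: time_in_top={top.time_in_zone:.1f} s, "
          f"entries={top.n_entries}, latency={top.latency_to_first_entry:.2f} s, "
          f"distance={eth.total_distance:.0f} cm, freezing={eth.total_freezing_time:.1f} s")
```

```
unbiased: time_in_top=142.0 s, entries=64, latency=7.56 s, distance=2121 cm, freezing=30.6 s
bottom-biased: time_in_top=41.8 s, entries=47, latency=9.28 s, distance=2045 cm, freezing=0.0 s
```

The downward drift (4 cm/s) cuts time in the top by ~3.4× at similar total
distance — the bottom-dwelling signature the novel tank test is designed to
detect.

The same workflows are exposed as a CLI
(`zebratrack simulate | ethogram | noveltank | mirror | socialpref | shoal |
rhythm | geneset | stats`), each reading the standard trajectory CSV
(`video_id, fish_id, frame, t_s, x, y`) or counts TSV and writing endpoint
tables.

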