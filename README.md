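# paracortex

Stochastic on-lattice simulation of T cell motility, chemotaxis and
trafficking in the lymph node paracortex.

T cells hunting for their cognate antigen perform a random walk through
the densely packed paracortex (T zone), entering from the blood through
high endothelial venules and leaving through discrete exit portals into
the lymphatic sinuses. The transit statistics of this traffic — a mean
residence time of 12–24 h, and its dramatic modulation during an immune
response — shape the size and timing of T cell activation. This package
is for computational immunologists who want to simulate these processes
at the 10⁴–10⁵-cell scale: it implements a crowding-aware lattice walk
(at most two cells per site, double occupancy for a single step to let
cells pass), a probabilistic chemotaxis scheme, discrete-portal egress
with an automatically calibrated portal count, and an
inflammation–vascularity ODE sub-model that drives the expansion and
contraction of the population.

## The model in brief

- **Motility.** Persistent random walk on a cubic lattice (6.3 µm
  spacing, 15 s steps): stay with probability p₀, else jump to a Moore
  neighbour with probability ∝ exp(κ cos φ)/|u|, where φ is the angle to
  a slowly relaxing heading. Defaults are calibrated to a mean speed of
  15 µm·min⁻¹ and motility coefficient C_m = 55 µm²·min⁻¹.
- **Chemotaxis.** An attraction vector **C** mixes a chemotaxis-only
  distribution p_c(i) ∝ cos²θᵢ/|u(i)| (counter-directed jumps zeroed)
  into the walk with weight α = min(1, |**C**|). Exit portals attract
  with the bounded inverse square g(r) = min(1, K_E/r²); multiple
  sources add vectorially.
- **Trafficking.** Cells enter within radius 0.7 R of the blob centre and
  leave from the 27-site Moore neighbourhoods of exit portals with
  probability P_E = 0.02 per step. The steady-state portal count follows
  the calibrated law N_E = round(max(β(K_E), 0.5) · (0.02/P_E) ·
  a·N^b / T_res).
- **Inflammation.** An inflammation signal A(t) drives growth-factor
  production, a Hill function of its concentration grows relative
  vascularity V, and influx scales as F_in = V·N₀/T_res.

See `docs/methods.md` for the full model description, parameter tables
and numerical choices.

## Worked example

Steady-state trafficking of a 10 000-cell blob at a 12 h residence time,
then the mean transit time of cells that entered between 24 h and 72 h:

```python
import numpy as np
from paracortex import SimulationConfig, run_simulation, transit_statistics

config = SimulationConfig(n0=10_000, t_res_min=720.0, duration_days=6.0, seed=11)
res = run_simulation(config)
mean_min, hist = transit_statistics(res.transit_log, burn_in_h=24.0,
                                    entry_cutoff_h=72.0)
print(f"portals: {len(res.portals)}")
print(f"population band: {res.population.n.min()}-{res.population.n.max()}")
print(f"mean transit: {mean_min / 60.0:.2f} h")
```

```
portals: 7
population band: 9791-10015
mean transit: 11.84 h
```

The automatically managed portal count (≈7 for 10 k cells) holds the
population within a few percent of N₀, and the measured residence time
reproduces the configured 12 h. The chemotaxis index of the calibrated
walk:

```python
from paracortex import chemotaxis_index

ci_dir, _ = chemotaxis_index(1.0, mode="directional", rng=np.random.default_rng(0))
ci_std, _ = chemotaxis_index(0.0, mode="standard", rng=np.random.default_rng(1))
print(f"directional CI at |C|=1: {ci_dir:.2f}   apparent CI at |C|=0: {ci_std:.2f}")
```

```
directional CI at |C|=1: 0.74   apparent CI at |C|=0: 0.54
```

At full chemotactic influence the directional index saturates at
1/1.361 ≈ 0.74 (every jump has a positive component along the attraction;
the path-length weighting sets the ceiling), while the *standard*
McCutcheon index of a chemotaxis-free walk is far from zero at short
windows — the reason the directional variant exists.

A command-line interface mirrors the library:

```bash
paracortex run --n0 10000 --days 6 --seed 11 --out run
paracortex ci-sweep --strengths 0,0.25,0.5,0.75,1 --seed 3
paracortex scenario-retention --k-e 2 --seed 5
```

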