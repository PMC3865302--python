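"""Simulate the study worlds and write them to disk.

Builds the default nonstationary world — a 50x50 one-degree grid whose
log-log fire-population slope follows a sigmoid crossing zero mid-grid —
plus a constant-coefficient (stationary) null world, and writes both as
flat CSV cell tables under results/.
"""

from pathlib import Path

from firegwr.grid_data import write_grid
from firegwr.synthetic import SyntheticScenario, simulate_gwr_world, simulate_stationary_world

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    ds, truth = simulate_gwr_world(SyntheticScenario(seed=SEED))
    write_grid(ds, OUT / "world_nonstationary.csv")
    print(f"nonstationary world: {ds.n} retained cells "
          f"({ds.n_removed_mask} non-combustible removed, "
          f"{truth.n_clipped} burned areas clipped at the cell area)")
    print(f"  true slope surface range: {truth.beta1.min():.2f} .. {truth.beta1.max():.2f}")

    null_ds, _ = simulate_stationary_world(400, beta0=0.5, beta1=1.0, noise_sd=0.5, seed=SEED)
    write_grid(null_ds, OUT / "world_stationary.csv")
    print(f"stationary null world: {null_ds.n} cells, constant slope 1.0")


if __name__ == "__main__":
    main()
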