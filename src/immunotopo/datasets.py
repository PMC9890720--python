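"""Bundled worked-example data: published cross-tabulations.

These are the printed cross-tabulations from a published immunohistochemical
study of a squamous-differentiated bladder-cancer TMA cohort (n = 114):
immune-marker densities dichotomized at the cohort median, and hot / cold /
excluded immune-topography calls, tabulated against clinico-pathological
and molecular status (tumour subtype, FGFR3 mutation, PD-L1 CPS, Ki67 and
perforin density). They serve as ready-made inputs for the statistics
battery — the underlying images are not public, but the tables are, so the
association analysis can be recomputed end to end from these counts.

Each entry maps a short name to ``(counts, test)`` where ``counts`` is a
row-major list (rows = the immune variable's levels, columns = the status
variable's levels) and ``test`` names the appropriate statlab routine.
"""

from __future__ import annotations

import numpy as np

from .statlab import ContingencyTable

__all__ = ["published_crosstabs", "crosstab"]

# rows x cols; 2x2 rows are (low, high) density, 3x2 rows are (hot, cold,
# excluded); columns are the status variable's two levels.
_CROSSTABS: dict[str, tuple[list[list[int]], str]] = {
    # CD8 density (low/high at 291.6 cells/mm^2) vs clinico-pathology
    "cd8_density_vs_age": ([[23, 27], [27, 26]], "chi_square"),
    "cd8_density_vs_sex": ([[24, 24], [26, 28]], "chi_square"),
    "cd8_density_vs_subtype": ([[38, 27], [15, 26]], "chi_square"),
    "cd8_density_vs_grade": ([[16, 14], [32, 39]], "chi_square"),
    "cd8_density_vs_stage": ([[5, 10], [40, 43]], "chi_square"),
    "cd8_density_vs_nodal": ([[29, 33], [8, 12]], "chi_square"),
    "cd8_density_vs_lymphatic": ([[18, 20], [8, 11]], "chi_square"),
    # marker density (low/high at cohort median) vs FGFR3 mutation (neg, pos)
    "cd3_density_vs_fgfr3": ([[22, 4], [33, 3]], "chi_square"),
    "cd4_density_vs_fgfr3": ([[26, 3], [25, 3]], "chi_square"),
    "cd8_density_vs_fgfr3": ([[20, 5], [31, 1]], "chi_square"),
    "cd68_density_vs_fgfr3": ([[27, 1], [27, 5]], "chi_square"),
    "cd79a_density_vs_fgfr3": ([[24, 6], [31, 1]], "chi_square"),
    "cd163_density_vs_fgfr3": ([[27, 5], [26, 2]], "chi_square"),
    "perforin_density_vs_fgfr3": ([[13, 4], [32, 1]], "chi_square"),
    # marker density vs PD-L1 CPS (<10, >=10)
    "cd3_density_vs_cps": ([[46, 3], [37, 11]], "chi_square"),
    "cd4_density_vs_cps": ([[44, 4], [35, 10]], "chi_square"),
    "cd8_density_vs_cps": ([[43, 3], [35, 11]], "chi_square"),
    "cd68_density_vs_cps": ([[46, 4], [35, 10]], "chi_square"),
    "cd79a_density_vs_cps": ([[45, 5], [38, 9]], "chi_square"),
    "cd163_density_vs_cps": ([[47, 4], [35, 10]], "chi_square"),
    "perforin_density_vs_cps": ([[39, 4], [33, 7]], "chi_square"),
    # immune topography (hot, cold, excluded) vs PD-L1 CPS (<10, >=10)
    "topo_cd3_cd4_vs_cps": ([[19, 9], [25, 2], [35, 3]], "fisher"),
    "topo_cd3_cd8_vs_cps": ([[20, 9], [26, 3], [32, 2]], "fisher"),
    "topo_cd79a_vs_cps": ([[4, 3], [8, 1], [71, 10]], "fisher"),
    "topo_cd68_cd163_vs_cps": ([[18, 10], [26, 4], [37, 0]], "fisher"),
    "topo_all_immune_vs_cps": ([[18, 10], [28, 3], [31, 1]], "fisher"),
    # immune topography vs Ki67 density (low/high at 509.5 cells/mm^2)
    "topo_cd3_cd4_vs_ki67": ([[8, 18], [17, 12], [19, 18]], "chi_square"),
    "topo_cd3_cd8_vs_ki67": ([[7, 20], [18, 13], [19, 15]], "chi_square"),
    "topo_cd79a_vs_ki67": ([[3, 6], [5, 2], [39, 41]], "chi_square"),
    "topo_cd68_cd163_vs_ki67": ([[11, 16], [18, 11], [17, 21]], "chi_square"),
    "topo_all_immune_vs_ki67": ([[8, 20], [16, 16], [19, 12]], "chi_square"),
    # immune topography vs perforin density (low/high at 9.0 cells/mm^2)
    "topo_cd3_cd4_vs_perforin": ([[9, 17], [19, 9], [17, 18]], "chi_square"),
    "topo_cd3_cd8_vs_perforin": ([[7, 19], [21, 9], [17, 16]], "chi_square"),
    "topo_cd79a_vs_perforin": ([[5, 3], [4, 2], [37, 41]], "chi_square"),
    "topo_cd68_cd163_vs_perforin": ([[12, 15], [18, 10], [15, 21]], "chi_square"),
    "topo_all_immune_vs_perforin": ([[11, 16], [19, 12], [15, 15]], "chi_square"),
}


def crosstab(name: str) -> tuple[ContingencyTable, str]:
    """One published cross-tabulation by name: (table, recommended test)."""
    counts, test = _CROSSTABS[name]
    return ContingencyTable(np.asarray(counts)), test


def published_crosstabs() -> dict[str, tuple[ContingencyTable, str]]:
    """All bundled cross-tabulations, keyed by short descriptive name."""
    return {name: crosstab(name) for name in _CROSSTABS}
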