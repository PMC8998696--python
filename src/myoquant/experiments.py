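"""End-to-end experiment recipes on synthetic cohorts.

These functions wire the generator and the measurement modules together the
way the analyses are meant to be run: synthesize a PRE/POST cohort with a
planted effect, push every section through segmentation and measurement,
and compute the cohort-level statistic.  They are used both by the test
suite and for reproducing the headline numbers.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .capillaries import capillary_fiber_contacts, detect_capillaries, fiber_capillary_indices
from .enzymes import enzyme_table
from .integration import global_indices, index_correlations
from .lipids import detect_droplets, droplet_depletion, lipid_index
from .morphometry import analyze_section
from .synthgen import SectionParams, generate_cohort


def _design(n_subjects: int, group: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject": f"{group}_S{i + 1:02d}", "group": group, "time": t}
            for i in range(n_subjects)
            for t in ("PRE", "POST")
        ]
    )


def droplet_depletion_experiment(
    n_subjects: int,
    retention: float,
    base_seed: int = 0,
    group: str = "37Y",
    n_fibers: int = 25,
    droplet_rate: float = 20.0,
) -> float:
    """Measured percent decrease in type-I fiber droplet number, PRE to POST.

    Generates one all-type-I section per subject and time with a mean of
    ``droplet_rate`` droplets per fiber PRE and ``droplet_rate × retention``
    POST, then runs segmentation, typing and droplet detection and computes
    the depletion statistic on the *detected* per-fiber counts.
    """
    pre = SectionParams(
        n_fibers=n_fibers, type_proportions={"I": 1.0}, droplet_rate=droplet_rate
    )
    post = replace(pre, droplet_rate=droplet_rate * retention)
    cohort = generate_cohort(
        _design(n_subjects, group), {(group, "PRE"): pre, (group, "POST"): post}, base_seed
    )
    counts: dict[str, list[int]] = {"PRE": [], "POST": []}
    for section, _truth in cohort:
        lab, fibers = analyze_section(section)
        droplets = detect_droplets(section["oro"], lab, section.pixel_scale)
        li = lipid_index(droplets, fibers).merge(
            fibers[["fiber_id", "fiber_type"]], on="fiber_id"
        )
        counts[section.time].extend(li.loc[li["fiber_type"] == "I", "n_droplets"])
    return droplet_depletion(counts["PRE"], counts["POST"])


def section_global_indices(section) -> pd.DataFrame:
    """Full per-fiber pipeline on one section: LC, ∑LD area and Int-SDH.

    All channels of a synthetic section share one geometry, so the serial-
    section correspondence is the identity and the three measurement tables
    join directly on fiber_id.
    """
    lab, fibers = analyze_section(section)
    droplets = detect_droplets(section["oro"], lab, section.pixel_scale)
    lip = lipid_index(droplets, fibers)
    enz = enzyme_table(section, lab, fibers)
    caps = detect_capillaries(section["cd31"], section.pixel_scale)
    contacts, fiber_lc = capillary_fiber_contacts(caps, lab, pixel_scale=section.pixel_scale)
    cap_idx = fiber_capillary_indices(contacts, fibers, fiber_lc)
    out = global_indices(fibers, cap_idx, lip, enz)
    out["subject"] = section.subject
    out["group"] = section.group
    out["time"] = section.time
    return out


def correlation_structure_experiment(
    n_subjects: int = 6,
    coupling_pre: float = 0.8,
    coupling_post: float = 0.0,
    base_seed: int = 0,
    group: str = "37Y",
    n_fibers: int = 25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """PRE/POST cohort with coordinated (PRE) vs independent (POST) indices.

    PRE sections couple droplet content, SDH activity and capillary contact
    through a shared per-fiber latent score; POST sections decouple them.
    Returns the pairwise Pearson correlations per time × fiber-type cell,
    fibers pooled across subjects.
    """
    pre = SectionParams(n_fibers=n_fibers, coupling=coupling_pre)
    post = replace(pre, coupling=coupling_post)
    cohort = generate_cohort(
        _design(n_subjects, group), {(group, "PRE"): pre, (group, "POST"): post}, base_seed
    )
    tables = [section_global_indices(section) for section, _ in cohort]
    pooled = pd.concat(tables, ignore_index=True)
    return index_correlations(pooled, by=["time", "fiber_type"], alpha=alpha)
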