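"""Published worked example of the five-index evaluation scheme.

Six clusterings of correlation-thresholded graphs for an HIV-positive
cohort (Louvain vs. integrity-driven NBR-Clust at 15, 20 and 64
attributes) with their printed index scores.  Used as input data for the
ranking tests.
"""

from cohortnet.validity import ScoreCard

WORKED_EXAMPLE_ROWS = [
    # (clusterer, n_attributes, DB, silhouette, CH, gamma, C-index)
    ("louvain", 15, 6.5642, -0.2268, 8.3909, 0.1874, 0.4581),
    ("louvain", 20, 5.5995, 0.0407, 18.7714, 0.3495, 0.3985),
    ("louvain", 64, 4.4396, 0.0304, 18.2146, 0.1927, 0.3735),
    ("integrity", 15, 3.9165, -0.2125, 2.9952, -0.1096, 0.5888),
    ("integrity", 20, 2.8065, -0.1429, 5.3985, 0.1375, 0.5088),
    ("integrity", 64, 1.2588, 0.2572, 13.8216, 0.8112, 0.1389),
]


def worked_example_scorecards() -> list[ScoreCard]:
    return [
        ScoreCard(
            clustering_id=(clusterer, size),
            davies_bouldin=db,
            silhouette=sil,
            calinski_harabasz=ch,
            baker_hubert=bh,
            hubert_levine=hl,
        )
        for clusterer, size, db, sil, ch, bh, hl in WORKED_EXAMPLE_ROWS
    ]
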