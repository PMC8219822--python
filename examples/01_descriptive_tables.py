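"""Decade tables: annual article/participant counts and decade averages.

Loads the packaged decade aggregates (one row per year, 2010-2019, with
article and participant counts by study category) and prints the grand
totals, a percentage spot-check, and the decade averages.
"""

from thermorep import decade_averages, load_packaged_tables

tables = load_packaged_tables()

print(f"Articles 2010-2019: {sum(s.articles_total for s in tables)}")
print(f"Participants 2010-2019: {sum(s.participants_total for s in tables)}")

last = tables[-1]
pct = last.article_percentages()
print(
    f"{last.year}: {last.articles_women_only} women-only articles "
    f"({pct['articles_women_only']}%), {last.articles_men_only} men-only "
    f"({pct['articles_men_only']}%)"
)

avg = decade_averages(tables)
print(
    "Decade mean articles/year: "
    f"women-only {avg.loc['articles_women_only', 'mean']:.1f} "
    f"(SD {avg.loc['articles_women_only', 'sd']:.1f}), "
    f"men-only {avg.loc['articles_men_only', 'mean']:.1f} "
    f"(SD {avg.loc['articles_men_only', 'sd']:.1f})"
)
# The totals are the corpus size of the decade; the category means show
# how heavily study counts skew toward men-only designs.
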