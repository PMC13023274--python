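"""Map land cover from RGB imagery and account class areas in a region.

Renders a synthetic aerial image of a patchy six-class neighborhood
(0.6 m/pixel), runs the imagery workflow (denoise, K-means color
segmentation, polygonization, vegetation flagging, labeling by majority
overlap with the ground truth), and compares recovered class areas with
the truth.
"""

import shapely

import catrange as cr

cfg = cr.LandscapeSimConfig(extent=(0, 0, 90, 90), pixel_size=0.6, seed=3)
img, truth = cr.simulate_imagery(cfg)
k = len(truth.labels)

polys, seg = cr.segment_image(
    img, config=cr.SegmentationConfig(k=k, seed=0, denoise_strength=0.0)
)
table = cr.label_table_from_truth(polys, truth)
lc_map = cr.assign_labels(polys, table)

total = truth.total_area()
print(f"{'class':<20}{'truth (m2)':>12}{'recovered (m2)':>16}{'error':>8}")
for cls in sorted(truth.labels):
    t = truth.class_geometry(cls).area
    r = lc_map.class_geometry(cls).area
    print(f"{cls:<20}{t:>12.0f}{r:>16.0f}{100 * abs(r - t) / total:>7.2f}%")

region = shapely.Point(45, 45).buffer(25, quad_segs=64)
areas = cr.class_areas(lc_map, region)
print(f"\nwithin a 25 m circle at the map center ({region.area:.0f} m2):")
print(f"  vegetated ('green') area: {areas['Green']:.0f} m2")
print(f"  all open areas:           {areas['Open all']:.0f} m2")
print("\nErrors come only from boundary pixels, so each class should recover")
print("its area to within ~2% of the mapped area on noise-free imagery.")
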