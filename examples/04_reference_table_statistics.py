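"""Recompute the summary rows of the bundled field-trial tables.

Ten hand-harvested plants per growth stage carry tape/scan-measured head
volumes and visible leaf areas next to the values this measurement method
produces on ground-truth and on network-predicted masks. All summary numbers
(mean, population SD as percent of mean, mean accuracy) are recomputed here
from the per-plant columns — nothing is stored pre-aggregated.
"""

import cabbagemorph as cm

report = cm.reproduce_tables()

v48 = report["volume_bbch48"]
print("Head volume, mature stage (BBCH 48), n = 10 plants")
print(f"  measured   : mean {v48['measured_mean']:.4f} m³, SD {v48['measured_sd_percent']:.1f} %")
print(f"  calculated : mean {v48['calculated_mean']:.4f} m³, accuracy {v48['calculated_mean_accuracy']:.1f} %")
print(f"  detected   : mean {v48['detected_mean']:.4f} m³, accuracy {v48['detected_mean_accuracy']:.1f} %")

la48 = report["leaf_area_bbch48"]
print("Visible leaf area, mature stage (BBCH 48)")
print(f"  {la48['leaves_visible_mean']:.1f} visible leaves/plant, "
      f"measured LA {la48['measured_mean']:.2f} m², "
      f"calculated {la48['calculated_mean']:.2f} m² "
      f"(accuracy {la48['calculated_mean_accuracy']:.1f} %)")
print(f"  area per visible leaf: {la48['area_per_leaf_measured']:.3f} m²")
# 'calculated' is the method on ground-truth masks (its ceiling);
# 'detected' adds the segmentation network's errors on top.
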