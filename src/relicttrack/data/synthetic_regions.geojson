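{
 "type": "FeatureCollection",
 "description": "SYNTHETIC region definitions. The breeding colony is the published capture site; the bay polygons are approximate hand-drawn rectangles bounding the coastal wintering areas (no authoritative polygons are published). Coordinates are lon,lat WGS84.",
 "features": [
  {
   "type": "Feature",
   "properties": {"name": "Breeding colony", "role": "breeding", "radius_km": 20.0},
   "geometry": {"type": "Point", "coordinates": [109.870, 39.138]}
  },
  {
   "type": "Feature",
   "properties": {"name": "Bohai Bay", "role": "wintering"},
   "geometry": {"type": "Polygon", "coordinates": [[
     [117.20, 37.80], [119.60, 37.80], [119.60, 39.70],
     [117.20, 39.70], [117.20, 37.80]
   ]]}
  },
  {
   "type": "Feature",
   "properties": {"name": "Laizhou Bay", "role": "wintering"},
   "geometry": {"type": "Polygon", "coordinates": [[
     [118.00, 36.80], [120.30, 36.80], [120.30, 37.75],
     [118.00, 37.75], [118.00, 36.80]
   ]]}
  },
  {
   "type": "Feature",
   "properties": {"name": "Yellow Sea coast", "role": "wintering"},
   "geometry": {"type": "Polygon", "coordinates": [[
     [119.90, 35.00], [121.30, 35.00], [121.30, 36.60],
     [119.90, 36.60], [119.90, 35.00]
   ]]}
  }
 ]
}
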