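{
  "type": "FeatureCollection",
  "name": "plastrend default ocean-basin boundaries",
  "description": "Editable six-basin partition used for station assignment and per-basin scaling of the expected-concentration field. Simplified boundaries: equator splits the Atlantic and Pacific north/south; 20E separates Atlantic from Indian; 147E separates Indian from Pacific south of the equator (100E north of it); a Central-American diagonal separates the Atlantic from the Pacific; the Mediterranean is a priority box ahead of the Atlantic. Features are tested in 'priority' order and the first covering polygon wins.",
  "features": [
    {
      "type": "Feature",
      "properties": {"basin": "Mediterranean", "priority": 0},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[[-6.0, 30.0], [36.0, 30.0], [36.0, 46.0], [-6.0, 46.0], [-6.0, 30.0]]]
      }
    },
    {
      "type": "Feature",
      "properties": {"basin": "NorthAtlantic", "priority": 1},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[[-100.0, 90.0], [-100.0, 18.0], [-84.0, 8.0], [-77.0, 6.0], [-60.0, 0.0], [20.0, 0.0], [20.0, 90.0], [-100.0, 90.0]]]
      }
    },
    {
      "type": "Feature",
      "properties": {"basin": "SouthAtlantic", "priority": 2},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[[-70.0, 0.0], [20.0, 0.0], [20.0, -90.0], [-70.0, -90.0], [-70.0, 0.0]]]
      }
    },
    {
      "type": "Feature",
      "properties": {"basin": "NorthPacific", "priority": 3},
      "geometry": {
        "type": "MultiPolygon",
        "coordinates": [
          [[[100.0, 0.0], [180.0, 0.0], [180.0, 90.0], [100.0, 90.0], [100.0, 0.0]]],
          [[[-180.0, 0.0], [-60.0, 0.0], [-77.0, 6.0], [-84.0, 8.0], [-100.0, 18.0], [-100.0, 90.0], [-180.0, 90.0], [-180.0, 0.0]]]
        ]
      }
    },
    {
      "type": "Feature",
      "properties": {"basin": "SouthPacific", "priority": 4},
      "geometry": {
        "type": "MultiPolygon",
        "coordinates": [
          [[[147.0, 0.0], [180.0, 0.0], [180.0, -90.0], [147.0, -90.0], [147.0, 0.0]]],
          [[[-180.0, 0.0], [-70.0, 0.0], [-70.0, -90.0], [-180.0, -90.0], [-180.0, 0.0]]]
        ]
      }
    },
    {
      "type": "Feature",
      "properties": {"basin": "Indian", "priority": 5},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[[20.0, 30.0], [100.0, 30.0], [100.0, 0.0], [147.0, 0.0], [147.0, -90.0], [20.0, -90.0], [20.0, 30.0]]]
      }
    }
  ]
}
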